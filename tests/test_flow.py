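"""Analytic duct results and the depth-averaged planform solver."""

import numpy as np
import pytest

import vesselchip as vc
from vesselchip.flow import UL_PER_MIN


class TestSlitWallShear:
    def test_quarter_microliter_channel(self):
        assert vc.slit_wall_shear(0.5, 200, 50, 1e-3) == pytest.approx(0.10)
        assert vc.slit_wall_shear(1.0, 200, 50, 1e-3) == pytest.approx(0.20)

    def test_no_flow_no_shear(self):
        assert vc.slit_wall_shear(0.0, 200, 50, 1e-3) == 0.0

    def test_nonpositive_inputs_rejected(self):
        for bad in [(-0.5, 200, 50, 1e-3), (0.5, 0, 50, 1e-3),
                    (0.5, 200, -50, 1e-3), (0.5, 200, 50, 0.0)]:
            with pytest.raises(ValueError):
                vc.slit_wall_shear(*bad)

    def test_low_aspect_warns(self):
        with pytest.warns(UserWarning, match="aspect"):
            vc.slit_wall_shear(0.5, 60, 50, 1e-3)


class TestRectDuctSeries:
    def test_bulk_mean_velocity(self):
        # Q/(w h): 0.5 uL/min over 200x50 um -> 0.833 mm/s
        y = np.linspace(-99, 99, 199)
        z = np.linspace(-24.5, 24.5, 49)
        u = vc.rect_duct_velocity(y[:, None], z[None, :], 0.5, 200, 50)
        mean = np.mean(u)  # uniform sampling over the cross-section
        expect = 0.5 * UL_PER_MIN / (200e-6 * 50e-6) * 1e3
        assert expect == pytest.approx(0.8333, abs=2e-4)
        assert mean == pytest.approx(expect, rel=0.01)

    def test_slit_limit_centerline_to_mean_ratio(self):
        # w >> h: mid-height centerline velocity -> 1.5 x bulk mean
        # (sidewall correction decays as O(h/w))
        u0 = vc.rect_duct_velocity(0.0, 0.0, 0.5, 10000, 50)
        bulk = 0.5 * UL_PER_MIN / (10000e-6 * 50e-6) * 1e3
        assert u0 / bulk == pytest.approx(1.5, rel=0.01)
        u1 = vc.rect_duct_velocity(0.0, 0.0, 0.5, 2500, 50)
        bulk1 = 0.5 * UL_PER_MIN / (2500e-6 * 50e-6) * 1e3
        assert abs(u0 / bulk - 1.5) < abs(u1 / bulk1 - 1.5)

    def test_profile_symmetric(self):
        prof = vc.rect_duct_profile(0.5, 200, 50, n_bins=40)
        assert np.allclose(prof.speed_mm_s, prof.speed_mm_s[::-1], rtol=1e-10)


class TestShearFromProfile:
    def test_parabolic_depth_profile_recovers_slit_value(self):
        prof = vc.slit_depth_profile(0.5, 200, 50, n_bins=25)
        tau = vc.shear_from_profile(prof, vc.get_fluid("pbs"))
        assert tau == pytest.approx(0.10, abs=1e-6)

    def test_plug_profile_zero_shear(self):
        prof = vc.VelocityProfile(coord_um=np.linspace(2.5, 47.5, 10),
                                  speed_mm_s=np.full(10, 1.0),
                                  counts=np.zeros(10, dtype=int),
                                  span_um=(0.0, 50.0))
        assert vc.shear_from_profile(prof, vc.get_fluid("pbs")) == \
            pytest.approx(0.0, abs=1e-12)

    def test_linear_in_flow_rate_for_newtonian(self):
        t1 = vc.shear_from_profile(vc.slit_depth_profile(0.5, 200, 50),
                                   vc.get_fluid("pbs"))
        t2 = vc.shear_from_profile(vc.slit_depth_profile(1.0, 200, 50),
                                   vc.get_fluid("pbs"))
        assert t2 == pytest.approx(2.0 * t1)

    def test_sparse_profile_rejected(self):
        prof = vc.VelocityProfile(coord_um=np.array([10.0, 25.0]),
                                  speed_mm_s=np.array([1.0, 1.2]),
                                  counts=np.zeros(2, dtype=int),
                                  span_um=(0.0, 50.0))
        with pytest.raises(ValueError, match="sparse"):
            vc.shear_from_profile(prof, vc.get_fluid("pbs"))


class TestPlanformSolver:
    def test_spanwise_profile_matches_duct_series(self, straight_flow):
        prof = vc.spanwise_profile(straight_flow, 1.0, 0.1, 40)
        series = vc.rect_duct_profile(0.5, 200, 50, n_bins=40,
                                      depth_averaged=True)
        err = np.nanmax(prof.speed_mm_s) / series.speed_mm_s.max() - 1.0
        assert abs(err) <= 0.02

    def test_flux_conserved_across_sections(self, straight_flow):
        rng = np.random.default_rng(0)
        for s in rng.uniform(0.1, 1.9, size=10):
            assert straight_flow.flux_at_station(float(s)) == \
                pytest.approx(0.5, rel=0.005)

    def test_no_slip_near_walls(self, straight_flow):
        g = straight_flow.grid
        near_wall = g.mask & (g.wall_distance_um <= 5.0)
        interior = g.mask & (g.wall_distance_um > 50.0)
        assert straight_flow.speed_mm_s[near_wall].max() < \
            0.25 * straight_flow.speed_mm_s[interior].max()

    def test_newtonian_limit_of_carreau(self, straight_grid, straight_flow):
        flat = vc.FluidModel(name="flat", density=1000.0, law="carreau",
                             eta_0=1e-3, eta_inf=1e-3, lam=1.0, n_index=0.5)
        f2 = vc.solve_planform(straight_grid, flat, 0.5)
        scale = np.abs(straight_flow.vx).max()
        assert np.abs(f2.vx - straight_flow.vx).max() / scale <= 1e-10
        assert np.abs(f2.vy - straight_flow.vy).max() / scale <= 1e-10

    def test_velocity_linear_in_flow_rate(self, straight_grid, straight_flow):
        f2 = vc.solve_planform(straight_grid, vc.get_fluid("pbs"), 1.0)
        scale = np.abs(straight_flow.vx).max()
        assert np.abs(f2.vx - 2.0 * straight_flow.vx).max() / scale <= 1e-9

    def test_grid_refinement_converged(self, straight_geom, straight_flow):
        fine = vc.solve_planform(vc.rasterize(straight_geom, 2.5),
                                 vc.get_fluid("pbs"), 0.5)
        c0 = np.nanmax(vc.spanwise_profile(straight_flow, 1.0, 0.1, 40).speed_mm_s)
        c1 = np.nanmax(vc.spanwise_profile(fine, 1.0, 0.1, 40).speed_mm_s)
        assert abs(c1 / c0 - 1.0) < 0.01

    def test_nonpositive_flow_rate_rejected(self, straight_grid):
        with pytest.raises(ValueError):
            vc.solve_planform(straight_grid, vc.get_fluid("pbs"), 0.0)


class TestConstriction:
    def test_half_blockage_doubles_speed(self, thrombus_scene):
        clot = thrombus_scene.geometry.defects[0]
        ratio = vc.constriction_speedup(thrombus_scene.flow, clot)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_three_quarter_blockage_quadruples_speed(self):
        geom = vc.build_serpentine(segment_length_mm=2.0, n_segments=1)
        clot = vc.Defect(kind="clot", path_position_mm=1.4,
                         spanwise_extent=0.75, axial_extent_um=200.0)
        geom = vc.add_defect(geom, clot)
        flow = vc.solve_planform(vc.rasterize(geom, 5.0),
                                 vc.get_fluid("pbs"), 0.5)
        # flux conservation oracle: Q through remaining width -> ratio 4
        assert vc.constriction_speedup(flow, clot) == pytest.approx(4.0,
                                                                    rel=0.10)

    def test_foreign_defect_rejected(self, straight_flow):
        clot = vc.Defect(kind="clot", path_position_mm=1.0)
        with pytest.raises(ValueError, match="not part"):
            vc.constriction_speedup(straight_flow, clot)


class TestBend:
    def test_inner_side_faster_than_outer(self, bend_flow_blood):
        inner, outer = vc.bend_speed_asymmetry(bend_flow_blood, 0)
        assert inner > outer

    def test_missing_bend_rejected(self, straight_flow):
        with pytest.raises(ValueError, match="no bend"):
            vc.bend_speed_asymmetry(straight_flow, 0)
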