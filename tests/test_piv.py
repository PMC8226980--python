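"""Normalized cross-correlation PIV: shifts, filtering, projections, and
consistency with the simulated flow and the tracking path."""

import numpy as np
import pytest
from scipy.ndimage import shift as ndshift

import vesselchip as vc


class TestShiftRecovery:
    def test_integer_shift_recovered_exactly(self, speckle_texture):
        a = speckle_texture
        b = np.roll(a, (1, 3), axis=(0, 1))
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        assert f.valid.any()
        assert np.all(f.du_px[f.valid] == 3.0)
        assert np.all(f.dv_px[f.valid] == 1.0)
        assert np.all(f.peak[f.valid] >= 1.0 - 1e-9)

    def test_self_correlation_zero_field(self, speckle_texture):
        f = vc.piv_pair(speckle_texture, speckle_texture, 32, 64, 0.5)
        assert np.all(f.du_px[f.valid] == 0.0)
        assert np.all(f.dv_px[f.valid] == 0.0)

    def test_subpixel_shift_within_tenth_pixel(self, speckle_texture):
        a = speckle_texture
        b = ndshift(a, (0.0, 2.5), order=3, mode="wrap")
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        assert abs(f.du_px[f.valid].mean() - 2.5) <= 0.1

    def test_equivariance_under_common_shift(self, speckle_texture):
        a = speckle_texture
        b = np.roll(a, (0, 2), axis=(0, 1))
        f1 = vc.piv_pair(a, b, 32, 64, 0.5)
        a2 = np.roll(a, (0, 5), axis=(0, 1))
        b2 = np.roll(b, (0, 5), axis=(0, 1))
        f2 = vc.piv_pair(a2, b2, 32, 64, 0.5)
        ok = f1.valid & f2.valid
        assert np.allclose(f1.du_px[ok], f2.du_px[ok])

    def test_ncc_bounded(self, speckle_texture):
        a = speckle_texture
        b = np.roll(a, (2, 1), axis=(0, 1)) + \
            np.random.default_rng(0).normal(0, 50, a.shape)
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        assert np.all(f.peak <= 1.0 + 1e-12)
        assert np.all(f.peak >= -1.0 - 1e-12)

    def test_featureless_window_flagged_invalid(self):
        a = np.full((128, 128), 500.0)
        b = np.full((128, 128), 500.0)
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        assert not f.valid.any()

    def test_bad_parameters_rejected(self, speckle_texture):
        with pytest.raises(ValueError):
            vc.piv_pair(speckle_texture, speckle_texture[:-1], 32, 64, 0.5)
        with pytest.raises(ValueError):
            vc.piv_pair(speckle_texture, speckle_texture, 64, 32, 0.5)
        with pytest.raises(ValueError):
            vc.piv_pair(speckle_texture, speckle_texture, 32, 64, 1.5)


class TestFiltering:
    def test_clean_uniform_field_unchanged(self, speckle_texture):
        a = speckle_texture
        b = np.roll(a, (1, 3), axis=(0, 1))
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        g = vc.filter_field(f, snr_min=1.1, median_tol_px=2.0)
        ok = f.valid & g.valid
        assert ok.any()
        assert np.array_equal(g.du_px[ok], f.du_px[ok])
        assert not g.interpolated.any()

    def test_injected_outlier_replaced_by_median(self, speckle_texture):
        from dataclasses import replace

        a = speckle_texture
        b = np.roll(a, (0, 2), axis=(0, 1))
        f = vc.piv_pair(a, b, 32, 64, 0.5)
        du = f.du_px.copy()
        du[2, 3] = 11.0   # inject a spurious vector
        f2 = replace(f, du_px=du)
        g = vc.filter_field(f2, snr_min=1.0, median_tol_px=2.0)
        assert g.du_px[2, 3] == pytest.approx(2.0, abs=0.1)
        assert g.interpolated[2, 3]

    def test_all_invalid_field_returned_with_warning(self):
        a = np.full((128, 128), 500.0)
        f = vc.piv_pair(a, a, 32, 64, 0.5)
        with pytest.warns(UserWarning, match="no valid"):
            g = vc.filter_field(f)
        assert not g.valid.any()


class TestTemporalProjection:
    def test_single_frame_is_itself(self):
        frame = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(vc.temporal_projection(frame, "max"), frame)

    def test_moving_spot_leaves_streak(self):
        stack = np.zeros((5, 16, 32))
        for f in range(5):
            stack[f, 8, 4 + 5 * f] = 1.0
        proj = vc.temporal_projection(stack, "max")
        assert all(proj[8, 4 + 5 * f] == 1.0 for f in range(5))

    def test_max_mode_permutation_invariant(self):
        rng = np.random.default_rng(3)
        stack = rng.random((6, 8, 8))
        perm = stack[rng.permutation(6)]
        assert np.array_equal(vc.temporal_projection(stack, "max"),
                              vc.temporal_projection(perm, "max"))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            vc.temporal_projection(np.zeros((2, 4, 4)), "median")


class TestSimulationConsistency:
    def test_rendered_scene_closes_loop_under_ten_percent(self, thrombus_scene,
                                                          thrombus_frames):
        # PIV on frames rendered from the simulated field reproduces that
        # field: RMS residual < 10% of the mean speed
        frames, crop = thrombus_frames
        flow = thrombus_scene.flow
        fld = vc.piv_stack(frames, window_size=32, search_size=64, overlap=0.5,
                           pixel_size_um=1.0, dt_ms=2.0,
                           origin_um=(crop[0], crop[1]))
        fld = vc.mask_windows(fld, flow)
        fld = vc.filter_field(fld, snr_min=1.5, median_tol_px=1.0)
        rep = vc.compare_to_simulation(fld, flow)
        assert rep["relative_rms"] < 0.10
        assert rep["n_windows"] > 100

    def test_constricted_windows_faster_than_open(self, thrombus_scene,
                                                  thrombus_frames):
        frames, crop = thrombus_frames
        flow = thrombus_scene.flow
        fld = vc.piv_stack(frames, window_size=32, search_size=64, overlap=0.5,
                           pixel_size_um=1.0, dt_ms=2.0,
                           origin_um=(crop[0], crop[1]))
        fld = vc.mask_windows(fld, flow)
        fld = vc.filter_field(fld, snr_min=1.5, median_tol_px=1.0)
        clot = thrombus_scene.geometry.defects[0]
        p0, _ = thrombus_scene.geometry.point_at(clot.path_position_mm)
        inside = (np.abs(fld.x_um - p0[0]) <= 100.0) & fld.valid
        open_ref = (np.abs(fld.x_um - (p0[0] - 600.0)) <= 100.0) & fld.valid
        v_in = fld.speed_mm_s[inside].mean()
        v_open = fld.speed_mm_s[open_ref].mean()
        assert v_in > v_open
        # approximately twofold speed-up in the constriction
        assert v_in / v_open == pytest.approx(2.0, rel=0.2)

    def test_normalized_magnitude_in_unit_range(self, thrombus_scene,
                                                thrombus_frames):
        frames, crop = thrombus_frames
        fld = vc.piv_pair(frames[0], frames[1], 32, 64, 0.5,
                          pixel_size_um=1.0, dt_ms=2.0,
                          origin_um=(crop[0], crop[1]))
        mag = fld.normalized_magnitude()
        ok = np.isfinite(mag)
        assert ok.any()
        assert mag[ok].min() >= 0.0 and mag[ok].max() <= 1.0

    def test_disjoint_domains_rejected(self, thrombus_scene, speckle_texture):
        f = vc.piv_pair(speckle_texture, speckle_texture, 32, 64, 0.5,
                        origin_um=(1e6, 1e6))
        with pytest.raises(ValueError, match="overlap"):
            vc.compare_to_simulation(f, thrombus_scene.flow)

    def test_piv_and_tracking_speeds_agree(self, straight_flow):
        # two independent measurement paths on the same baseline scene
        spec = vc.SceneSpec(fluid_name="pbs", n_particles=40, n_frames=6,
                            seed=10)
        trajs = vc.advect_particles(straight_flow, spec)
        crop = (300.0, -110.0, 1300.0, 110.0)
        frames = vc.render_frames(trajs, straight_flow, spec, crop_um=crop)
        fld = vc.piv_stack(frames, window_size=32, search_size=64, overlap=0.5,
                           pixel_size_um=1.0, dt_ms=2.0,
                           origin_um=(crop[0], crop[1]))
        fld = vc.mask_windows(fld, straight_flow)
        fld = vc.filter_field(fld, snr_min=1.5)
        piv_speed = fld.speed_mm_s[fld.valid].mean()
        track_speed = np.mean([vc.mean_speed(t) for t in trajs if len(t) > 1])
        assert piv_speed == pytest.approx(track_speed, rel=0.15)
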