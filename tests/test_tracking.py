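"""Trajectory statistics, spot detection, and linking."""

import numpy as np
import pytest

import vesselchip as vc


def _traj(xs, ys, dt=2.0):
    t = np.arange(len(xs)) * dt
    return vc.Trajectory(0, t, np.asarray(xs, float), np.asarray(ys, float))


class TestMeanSpeed:
    def test_constant_motion_identity(self):
        # 1 mm/s = 2 um per 2 ms step
        tr = _traj([0, 2, 4, 6], [0, 0, 0, 0])
        assert vc.mean_speed(tr) == pytest.approx(1.0)

    def test_hand_arithmetic_two_steps(self):
        # steps 2 um and 4 um at 2 ms -> (1.0 + 2.0)/2 = 1.5 mm/s
        tr = _traj([0, 2, 6], [0, 0, 0])
        assert vc.mean_speed(tr) == pytest.approx(1.5)

    def test_pythagoras_single_step(self):
        # (0,0) -> (3,4) um: delta = 5 um, <v> = 2.5 mm/s
        tr = _traj([0, 3], [0, 4])
        assert vc.mean_speed(tr) == pytest.approx(2.5)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            vc.mean_speed(vc.Trajectory(0, [0.0], [1.0], [1.0]))

    @pytest.mark.parametrize("angle_deg", [0, 30, 90, 137, 250])
    def test_invariant_to_translation_and_rotation(self, angle_deg):
        rng = np.random.default_rng(0)
        xs = np.cumsum(rng.uniform(0.5, 3.0, 12))
        ys = np.cumsum(rng.normal(0, 0.5, 12))
        base = vc.mean_speed(_traj(xs, ys))
        a = np.radians(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        pts = (R @ np.vstack([xs, ys])) + np.array([[17.0], [-42.0]])
        assert vc.mean_speed(_traj(pts[0], pts[1])) == pytest.approx(base)


class TestScatteringAngles:
    def test_purely_axial_step_zero_angle(self):
        phi, summ = vc.scattering_angles(_traj([0, 2], [0, 0]), "x")
        assert phi[0] == pytest.approx(0.0)

    def test_purely_lateral_step_ninety_degrees(self):
        phi, _ = vc.scattering_angles(_traj([0, 0], [0, 2]), "x")
        assert phi[0] == pytest.approx(90.0)

    def test_inverse_sine_arithmetic(self):
        # lateral 1.0 um over delta 47.75 um -> asin(1/47.75) = 1.2 deg
        ax = np.sqrt(47.75**2 - 1.0**2)
        phi, _ = vc.scattering_angles(_traj([0, ax], [0, 1.0]), "x")
        assert phi[0] == pytest.approx(1.2, abs=0.001)

    def test_zero_length_steps_excluded_and_counted(self):
        tr = _traj([0, 0, 2], [0, 0, 0])
        phi, summ = vc.scattering_angles(tr, "x")
        assert summ.n_steps == 1
        assert summ.n_excluded == 1

    def test_angles_bounded(self):
        rng = np.random.default_rng(1)
        tr = _traj(np.cumsum(rng.uniform(-2, 3, 50)),
                   np.cumsum(rng.uniform(-2, 3, 50)))
        phi, _ = vc.scattering_angles(tr, "x")
        assert np.all((phi >= 0) & (phi <= 90))


class TestInteractionLength:
    def test_printed_angles_give_printed_lengths(self):
        # phi = 1.2 deg -> 4.8 mm; phi = 1.3 deg -> 4.4 mm (2 s.f.)
        assert round(vc.interaction_length(1.2, 100.0), 1) == 4.8
        assert round(vc.interaction_length(1.3, 100.0), 1) == 4.4

    def test_forty_five_degrees(self):
        assert vc.interaction_length(45.0, 100.0) == pytest.approx(0.1)

    def test_zero_angle_infinite_with_warning(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert vc.interaction_length(0.0, 100.0) == float("inf")

    def test_summary_field_filled(self):
        summ = vc.ScatterSummary(mean_deg=1.2, sd_deg=0.7, n_steps=100)
        L = vc.interaction_length(summ, 100.0)
        assert summ.interaction_length_mm == pytest.approx(L)


class TestDetection:
    def test_blank_frame_empty(self):
        frame = np.full((64, 64), 100, dtype=np.uint16)
        assert len(vc.detect_spots(frame, threshold=500)) == 0

    def test_five_gaussian_spots_recovered(self):
        rng = np.random.default_rng(5)
        truth = np.array([[12.3, 40.6], [50.1, 12.8], [90.7, 55.2],
                          [30.4, 80.9], [70.0, 90.5]])
        yy, xx = np.mgrid[0:128, 0:128]
        img = np.full((128, 128), 200.0)
        for x, y in truth:
            img += 5000.0 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.5**2))
        img += rng.normal(0, 20, img.shape)
        det = vc.detect_spots(img.astype(np.uint16), threshold=1500)
        assert len(det) == 5
        from scipy.spatial.distance import cdist
        d = cdist(truth, det)
        assert d.min(axis=1).max() < 0.3

    def test_close_spots_merged_deterministically(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.zeros((64, 64))
        for x, y in [(30.0, 30.0), (33.0, 30.0)]:   # closer than separation
            img += 5000.0 * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.5**2))
        det = vc.detect_spots(img, threshold=1500, min_separation_px=5)
        assert len(det) == 1   # merged, count reported via the return size

    def test_saturated_frame_warns(self):
        frame = np.zeros((32, 32), dtype=np.uint16)
        frame[10:13, 10:13] = np.iinfo(np.uint16).max
        with pytest.warns(UserWarning, match="saturated"):
            vc.detect_spots(frame, threshold=1000)


class TestLinking:
    def test_constant_velocity_single_track(self):
        dets = [np.array([[10.0 + 3 * f, 20.0]]) for f in range(8)]
        tracks = vc.link(dets, max_disp_px=5.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 8

    def test_gate_terminates_track(self):
        dets = [np.array([[10.0, 20.0]]), np.array([[12.0, 20.0]]),
                np.array([[40.0, 20.0]]), np.array([[42.0, 20.0]])]
        tracks = vc.link(dets, max_disp_px=5.0, min_length=2)
        assert len(tracks) == 2   # jump beyond the gate breaks the track

    def test_generated_scene_links_match_truth(self, straight_flow):
        spec = vc.SceneSpec(
            fluid_name="pbs", n_particles=20, n_frames=10,
            scatter=vc.ScatterModel(collision_rate=0.0, sigma_phi_deg=0.0),
            optics=vc.Optics(speckle_contrast=0.0, noise_sd=15.0),
            seed=6, seed_margin_um=30.0)
        truth = vc.advect_particles(straight_flow, spec)
        crop = (200.0, -110.0, 1200.0, 110.0)
        frames = vc.render_frames(truth, straight_flow, spec, crop_um=crop)
        dets = [vc.detect_spots(f, threshold=2000) for f in frames]
        tracks = vc.link(dets, max_disp_px=8.0, dt_ms=2.0, pixel_size_um=1.0,
                         origin_um=(crop[0] + 0.5, crop[1] + 0.5))
        # every linked step must match a single truth particle's motion
        correct = total = 0
        for tr in tracks:
            for k in range(len(tr) - 1):
                p0 = np.array([tr.x_um[k], tr.y_um[k]])
                p1 = np.array([tr.x_um[k + 1], tr.y_um[k + 1]])
                f0 = int(round(tr.t_ms[k] / 2.0))
                ids0 = [(np.hypot(t.x_um[f0] - p0[0], t.y_um[f0] - p0[1]), t.particle_id)
                        for t in truth if len(t) > f0]
                ids1 = [(np.hypot(t.x_um[f0 + 1] - p1[0], t.y_um[f0 + 1] - p1[1]), t.particle_id)
                        for t in truth if len(t) > f0 + 1]
                if ids0 and ids1:
                    total += 1
                    if min(ids0)[1] == min(ids1)[1]:
                        correct += 1
        assert total > 50
        assert correct / total >= 0.95

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            vc.link([np.array([[0.0, 0.0]])], max_disp_px=5.0)


class TestVelocityProfile:
    def test_tracks_on_analytic_parabola_recovered(self, straight_grid):
        # generator oracle: trajectories advected on an exact parabola
        w = 200.0
        rng = np.random.default_rng(8)
        trajs = []
        for k in range(120):
            d = rng.uniform(-90.0, 90.0)
            v = 1.25 * (1.0 - (d / 100.0) ** 2)   # mm/s
            x0 = rng.uniform(200.0, 800.0)
            xs = x0 + np.arange(8) * v * 2.0      # um per 2 ms
            trajs.append(vc.Trajectory(k, np.arange(8) * 2.0, xs,
                                       np.full(8, d)))
        prof = vc.velocity_profile(trajs, straight_grid, n_bins=10)
        d_bins = prof.coord_um - w / 2.0
        # interior bins only: edge bins are half-covered by the seeding range
        ok = (prof.counts > 2) & (np.abs(d_bins) <= 75.0)
        expect = 1.25 * (1.0 - (d_bins[ok] / 100.0) ** 2)
        # bin-averaged parabola differs from midpoint value by < 5%
        assert np.all(np.abs(prof.speed_mm_s[ok] / expect - 1.0) < 0.05)

    def test_empty_bins_nan_not_zero(self, straight_grid):
        tr = vc.Trajectory(0, [0.0, 2.0], [500.0, 502.0], [0.0, 0.0])
        prof = vc.velocity_profile([tr], straight_grid, n_bins=10)
        assert np.isnan(prof.speed_mm_s[prof.counts == 0]).all()
        assert np.isfinite(prof.speed_mm_s[prof.counts > 0]).all()

    def test_near_wall_slower_than_center(self, straight_flow):
        spec = vc.SceneSpec(fluid_name="pbs", n_particles=200, n_frames=25,
                            scatter=vc.ScatterModel(collision_rate=0.0,
                                                    sigma_phi_deg=0.0),
                            seed=3, seed_margin_um=10.0)
        trajs = vc.advect_particles(straight_flow, spec)
        prof = vc.velocity_profile(trajs, straight_flow.grid, n_bins=20)
        ok = prof.counts > 3
        speeds = prof.speed_mm_s[ok]
        coords = prof.coord_um[ok]
        near_wall = speeds[np.argmin(coords)]
        center = speeds[np.argmin(np.abs(coords - 100.0))]
        assert near_wall < center
        # maximum lies in the central third; profile symmetric within 3%
        arg = np.argmax(speeds)
        assert abs(coords[arg] - 100.0) <= 35.0
        d = coords - 100.0
        for k in range(len(d)):
            mirror = np.argmin(np.abs(d + d[k]))
            if abs(d[mirror] + d[k]) < 1.0:
                assert speeds[k] == pytest.approx(speeds[mirror], rel=0.03)


class TestCsvRoundTrip:
    def test_tracks_survive_io(self, tmp_path, straight_flow):
        spec = vc.SceneSpec(fluid_name="pbs", n_particles=5, n_frames=6,
                            seed=1)
        trajs = vc.advect_particles(straight_flow, spec)
        path = tmp_path / "tracks.csv"
        vc.tracks_to_csv(trajs, path)
        back = vc.tracks_from_csv(path)
        assert len(back) == len(trajs)
        for a, b in zip(trajs, back):
            assert np.allclose(a.x_um, b.x_um)
            assert np.allclose(a.y_um, b.y_um)
            assert np.allclose(a.t_ms, b.t_ms)
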