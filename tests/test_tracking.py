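"""Kalman estimator, intersection association and track lifecycle."""

import numpy as np
import pytest

from fura2track import (
    Channel,
    FrameSequence,
    InputError,
    JerkStats,
    SegmentationParams,
    Status,
    TrackingConfig,
    build_kalman,
    estimate_jerk_stats,
    gen_jerk_tracks,
    intersect_kernel,
    label_components,
    observability_rank,
    resolve_label,
    run_kalman_filter,
    run_tracking,
    segment_sequence,
)

T = 3.0


# ---------------------------------------------------------------------------
# jerk statistics
# ---------------------------------------------------------------------------

class TestEstimateJerkStats:
    def test_constant_positions_give_zero_sigma(self):
        tracks = [np.full((20, 2), 7.0)] * 3
        stats = estimate_jerk_stats(tracks, period=T)
        assert stats.sigma_jx == 0.0 and stats.sigma_jy == 0.0

    def test_cubic_trajectory_has_constant_jerk_hence_zero_sigma(self):
        t = np.arange(30, dtype=float)
        track = np.column_stack([t**3, 2 * t**3])
        stats = estimate_jerk_stats([track], period=T)
        assert stats.sigma_jx == pytest.approx(0.0, abs=1e-9)
        assert stats.sigma_jy == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_white_jerk_within_sampling_error(self):
        sjx, sjy = 0.0269, 0.0993
        tracks = gen_jerk_tracks(15, 100, sjx, sjy, period=T, seed=42)
        stats = estimate_jerk_stats(tracks, period=T)
        # SE of the mean-of-sample-stds ~ sigma / sqrt(2 (p-4) c)
        se_x = sjx / np.sqrt(2 * 96 * 15)
        se_y = sjy / np.sqrt(2 * 96 * 15)
        assert abs(stats.sigma_jx - sjx) < 3 * se_x
        assert abs(stats.sigma_jy - sjy) < 3 * se_y

    def test_short_series_raises(self):
        with pytest.raises(InputError):
            estimate_jerk_stats([np.zeros((4, 2))], period=T)

    def test_negative_sigma_rejected(self):
        with pytest.raises(InputError):
            JerkStats(-1.0, 0.1, 1, 10)


# ---------------------------------------------------------------------------
# Kalman model assembly
# ---------------------------------------------------------------------------

class TestBuildKalman:
    def test_transition_blocks(self):
        m = build_kalman(period=T)
        assert m.F[0, 1] == 3.0  # position-velocity coupling = T
        assert m.F[0, 2] == 4.5  # position-acceleration coupling = T^2/2
        assert m.F[3, 4] == 3.0 and m.F[3, 5] == 4.5
        np.testing.assert_array_equal(m.H, [[1, 0, 0, 0, 0, 0], [0, 0, 0, 1, 0, 0]])

    def test_q_equals_outer_product_recomputed_elementwise(self):
        m = build_kalman(JerkStats(0.0269, 0.0993, 15, 100), period=T)
        q = [
            T**3 * 0.0269 / 3,
            T**2 * 0.0269 / 2,
            T * 0.0269,
            T**3 * 0.0993 / 3,
            T**2 * 0.0993 / 2,
            T * 0.0993,
        ]
        expected = np.array([[qi * qj for qj in q] for qi in q])
        np.testing.assert_allclose(m.Q, expected, rtol=1e-15)

    def test_r_is_diagonal_of_squared_obs_sigmas(self):
        m = build_kalman(sigma_obs=(0.5, 0.25), period=T)
        np.testing.assert_array_equal(m.R, np.diag([0.25, 0.0625]))

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(InputError):
            build_kalman(sigma_obs=(0.0, 0.1))
        with pytest.raises(InputError):
            build_kalman(period=0.0)


class TestObservability:
    def test_position_observation_gives_full_rank(self):
        assert observability_rank(build_kalman(period=T)) == 6

    def test_zeroed_observation_gives_rank_zero(self):
        m = build_kalman(period=T)
        m.H = np.zeros((2, 6))
        assert observability_rank(m) == 0

    def test_observing_only_x_gives_rank_three(self):
        m = build_kalman(period=T)
        m.H = np.zeros((2, 6))
        m.H[0, 0] = 1.0  # x only: the y chain is unobservable
        assert observability_rank(m) == 3


# ---------------------------------------------------------------------------
# predict / correct
# ---------------------------------------------------------------------------

class TestPredictCorrect:
    def test_predict_advances_position_by_velocity_times_period(self):
        m = build_kalman(period=T)
        m.state = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        x, y = m.predict()
        assert x == pytest.approx(3.0) and y == 0.0

    def test_zero_state_predicts_zero(self):
        m = build_kalman(period=T)
        assert m.predict() == (0.0, 0.0)

    def test_repeated_prediction_follows_constant_acceleration_kinematics(self):
        x0, v0, a0 = 5.0, 2.0, -0.5
        m = build_kalman(period=T)
        m.state = np.array([x0, v0, a0, 0.0, 0.0, 0.0])
        for k in range(1, 6):
            x, _ = m.predict()
            t = k * T
            assert x == pytest.approx(x0 + v0 * t + a0 * t * t / 2, rel=1e-12)

    def test_correction_with_observation_equal_to_prediction_is_identity(self):
        m = build_kalman(period=T, initial_position=(10.0, 20.0))
        pred = m.predict()
        pos = m.correct(pred)
        assert pos == pytest.approx(pred, abs=1e-12)

    def test_huge_r_leaves_prediction_unchanged(self):
        m = build_kalman(period=T, initial_position=(10.0, 20.0))
        m.R = np.diag([1e12, 1e12])  # gain -> 0 in the R -> infinity limit
        pred = m.predict()
        pos = m.correct((500.0, -300.0))
        assert pos == pytest.approx(pred, abs=1e-6)

    def test_covariance_stays_symmetric_psd(self, rng):
        m = build_kalman(period=T)
        for _ in range(50):
            m.predict()
            m.correct(tuple(rng.normal(0, 10, 2)))
            np.testing.assert_allclose(m.P, m.P.T, atol=1e-10)
            assert np.linalg.eigvalsh(m.P).min() > -1e-9

    def test_noise_free_tracking_converges_to_observations(self):
        # constant-velocity truth observed exactly: corrected position
        # should sit on the observation to within 1e-6 px after burn-in
        truth = np.column_stack([10 + 0.4 * np.arange(40), 20 - 0.2 * np.arange(40)])
        est = run_kalman_filter(truth)
        err = np.abs(est[5:] - truth[5:]).max()
        assert err < 1e-6

    def test_prediction_error_decays_under_constant_acceleration(self):
        t = np.arange(60) * T
        truth = np.column_stack([5 + 0.3 * t + 0.01 * t**2 / 2, np.full(60, 30.0)])
        est = run_kalman_filter(truth)
        rms_early = np.sqrt(np.mean((est[1:10] - truth[1:10]) ** 2))
        rms_late = np.sqrt(np.mean((est[30:] - truth[30:]) ** 2))
        assert rms_late < rms_early


# ---------------------------------------------------------------------------
# intersection and label resolution
# ---------------------------------------------------------------------------

def _blob_grid(n_side=5, blob=3, pitch=6):
    """n_side x n_side grid of blob x blob squares, labels in raster order."""
    size = n_side * pitch + 2
    mask = np.zeros((size, size), bool)
    for r in range(n_side):
        for c in range(n_side):
            mask[1 + r * pitch : 1 + r * pitch + blob, 1 + c * pitch : 1 + c * pitch + blob] = True
    return label_components(mask)


class TestIntersectKernel:
    def test_kernel_over_one_blob_returns_its_label(self):
        # a 25-blob frame; the kernel overlaps exactly blob 22
        current = _blob_grid()
        kernel = np.zeros_like(current.binary)
        kernel[current.labels == 22] = True
        assert intersect_kernel(kernel, current) == {22}

    def test_no_overlap_returns_empty_set(self):
        current = _blob_grid()
        kernel = np.zeros_like(current.binary)
        assert intersect_kernel(kernel, current) == set()

    def test_kernel_straddling_two_blobs_returns_both(self):
        current = _blob_grid()
        kernel = np.zeros_like(current.binary)
        kernel[1:4, 1:10] = True  # spans blobs 1 and 2 of the first row
        assert intersect_kernel(kernel, current) == {1, 2}


class TestResolveLabel:
    def test_single_candidate_wins_regardless_of_prediction(self):
        current = _blob_grid()
        model = build_kalman(period=T, initial_position=(1000.0, 1000.0))
        assert resolve_label({7}, model, current, gate=3.0) == 7

    def test_prediction_inside_component_resolves_it(self):
        current = _blob_grid()
        x, y = current.centroid(13)
        model = build_kalman(period=T, initial_position=(x, y))
        assert resolve_label(set(), model, current, gate=3.0) == 13

    def test_two_candidates_resolved_by_nearest_centroid_within_gate(self):
        current = _blob_grid()
        xa, ya = current.centroid(1)
        model = build_kalman(period=T, initial_position=(xa + 0.6, ya + 0.6))
        assert resolve_label({1, 2}, model, current, gate=5.0) == 1

    def test_nothing_within_gate_is_missing(self):
        current = _blob_grid()
        model = build_kalman(period=T, initial_position=(29.0, 29.0))
        # prediction in the gap between blobs, gate too tight to reach one
        assert resolve_label(set(), model, current, gate=0.5) is None


# ---------------------------------------------------------------------------
# lifecycle
# ---------------------------------------------------------------------------

def _sequence_from_masks(masks):
    frames = (np.stack(masks).astype(np.uint8)) * 200
    return FrameSequence(frames + 20, channel=Channel.EX340)


def _disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


class TestLifecycle:
    def _run(self, visible_per_frame, rl=3, shape=(64, 64)):
        """Build a sequence where one disk appears per (x, y) in each frame list."""
        masks = [
            np.any([_disk_mask(shape, x, y, 5) for x, y in pts], axis=0)
            if pts
            else np.zeros(shape, bool)
            for pts in visible_per_frame
        ]
        seq = _sequence_from_masks(masks)
        params = SegmentationParams(w=16, open_radius=2)
        labeled = segment_sequence(seq, params)
        ratio = FrameSequence(
            np.ones_like(seq.frames, dtype=float), channel=Channel.RATIO
        )
        return run_tracking(
            labeled, ratio, selections="all", params=params, config=TrackingConfig(rl=rl)
        )

    def test_stationary_cell_stays_online_with_constant_centroid(self):
        res = self._run([[(30, 30)]] * 10)
        (track,) = res.tracks
        assert track.status is Status.ONLINE
        assert track.reliability_counter == 0
        assert len(track.positions) == 10
        assert np.ptp(track.positions, axis=0).max() < 0.01

    def test_vanishing_cell_goes_offline_at_rl_and_stays(self):
        # visible on frame 0 only; RL = 3: counter hits 3 on the third
        # missing frame and the track is retired from then on
        res = self._run([[(30, 30)]] + [[]] * 5, rl=3)
        (track,) = res.tracks
        assert track.status is Status.OFFLINE
        statuses = [r.status for r in track.history]
        assert statuses == ["ONLINE", "ONLINE", "ONLINE", "OFFLINE", "OFFLINE", "OFFLINE"]
        assert all(np.isnan(r.x) for r in track.history[1:])

    def test_reappearance_before_rl_resets_counter(self):
        pts = [[(30, 30)], [], [], [(31, 30)], [(31, 30)]]
        res = self._run(pts, rl=3)
        (track,) = res.tracks
        assert track.status is Status.ONLINE
        assert track.reliability_counter == 0
        found = [r.found_by for r in track.history]
        assert found[3] != "NONE" and found[1] == "NONE"

    def test_two_frame_sequence_executes_one_step(self):
        res = self._run([[(30, 30)], [(30, 31)]])
        (track,) = res.tracks
        assert len(track.history) == 2

    def test_empty_first_frame_with_select_all_gives_empty_result(self):
        res = self._run([[], [(30, 30)]])
        assert res.tracks == []

    def test_offline_is_absorbing_even_if_cell_returns(self):
        pts = [[(30, 30)], [], [], [], [(30, 30)], [(30, 30)]]
        res = self._run(pts, rl=3)
        (track,) = res.tracks
        assert track.status is Status.OFFLINE
        assert all(r.found_by == "NONE" for r in track.history[1:])


class TestEndToEndPhantom:
    def test_associations_and_profiles_match_ground_truth(self, benchmark_phantom):
        from fura2track import compute_window_size, make_ratio_sequence

        res = benchmark_phantom
        areas = [np.pi * r * r for r in res.radii]
        params = SegmentationParams(w=compute_window_size(areas, 2.0))
        ratio = make_ratio_sequence(res.seq340, res.seq380)
        labeled = segment_sequence(res.seq340, params)
        out = run_tracking(labeled, ratio, "all", params, TrackingConfig(rl=3))
        assert len(out.tracks) == 30

        correct = total = 0
        cp_mses = []
        for track in out.tracks:
            first = track.history[0]
            d0 = np.hypot(
                res.positions[0, :, 0] - first.x, res.positions[0, :, 1] - first.y
            )
            cell = int(np.argmin(d0))
            frames, cps = [], []
            for rec in track.history:
                if rec.found_by == "NONE":
                    continue
                total += 1
                err = np.hypot(
                    res.positions[rec.frame, cell, 0] - rec.x,
                    res.positions[rec.frame, cell, 1] - rec.y,
                )
                if err < 5.0:
                    correct += 1
                frames.append(rec.frame)
                cps.append(rec.cp)
            cp_mses.append(np.mean((np.asarray(cps) - res.cp_truth[frames]) ** 2))
        assert correct / total >= 0.95
        assert max(cp_mses) < 1e-3
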