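import math

import numpy as np
import pytest

from motorkin.errors import InvalidInputError, InvalidParameterError
from motorkin.segmentation import (
    BOUND,
    EDGE_UNDEFINED,
    UNBOUND,
    NoiseFloor,
    SegmentationParams,
    StateSegmentation,
    Trajectory2D,
    apply_g0_merge_rule,
    classify_detachment_origin,
    compute_rolling_sd,
    detect_transitions,
    extract_dwells,
    fit_noise_floor,
    median_filter_trace,
    refine_transition_stepfit,
    segment_trajectory,
)
from conftest import make_step_trajectory


def brute_force_rolling_sd(on, off, half_window):
    """Independent windowed-variance oracle (explicit loop)."""
    n = len(on)
    out = np.full(n, np.nan)
    for i in range(half_window, n - half_window):
        w_on = on[i - half_window:i + half_window + 1]
        w_off = off[i - half_window:i + half_window + 1]
        out[i] = math.sqrt(np.var(w_on, ddof=1) + np.var(w_off, ddof=1))
    return out


def seg_from_labels(labels, frame_rate, traj=None, **kw):
    """Build a StateSegmentation directly from per-frame label codes."""
    from motorkin.segmentation import _dwells_from_labels, _transitions_from_dwells

    labels = np.asarray(labels, np.int8)
    dwells = _dwells_from_labels(labels, traj, frame_rate)
    return StateSegmentation(
        labels=labels, frame_rate=frame_rate,
        transitions=_transitions_from_dwells(dwells), dwells=dwells, **kw,
    )


class TestTrajectory2D:
    def test_time_consistency_enforced(self):
        with pytest.raises(InvalidInputError):
            Trajectory2D(np.arange(5), np.arange(5) * 0.5, np.zeros(5),
                         np.zeros(5), frame_rate=1000.0)

    def test_nonfinite_rejected(self):
        on = np.zeros(5)
        on[2] = np.nan
        with pytest.raises(InvalidInputError):
            Trajectory2D.from_positions(on, np.zeros(5), 1000.0)

    def test_nonconsecutive_frames_rejected(self):
        frame = np.array([0, 1, 3, 4])
        with pytest.raises(InvalidInputError):
            Trajectory2D(frame, frame / 1e3, np.zeros(4), np.zeros(4), 1e3)


class TestRollingSd:
    def test_constant_trajectory_zero(self):
        traj = Trajectory2D.from_positions(np.full(200, 3.0), np.full(200, -1.0),
                                           1000.0)
        sd = compute_rolling_sd(traj, half_window=20)
        assert np.all(np.isnan(sd[:20])) and np.all(np.isnan(sd[-20:]))
        np.testing.assert_allclose(sd[20:-20], 0.0, atol=1e-9)

    def test_alternating_signal_matches_brute_force(self):
        a = 7.0
        on = a * (-1.0) ** np.arange(300)
        off = np.zeros(300)
        traj = Trajectory2D.from_positions(on, off, 1000.0)
        sd = compute_rolling_sd(traj, half_window=20)
        oracle = brute_force_rolling_sd(on, off, 20)
        np.testing.assert_allclose(sd, oracle, rtol=1e-10)

    def test_random_signal_matches_brute_force(self):
        rng = np.random.default_rng(0)
        on, off = rng.standard_normal((2, 500)) * 5
        traj = Trajectory2D.from_positions(on, off, 1000.0)
        np.testing.assert_allclose(
            compute_rolling_sd(traj, 10),
            brute_force_rolling_sd(on, off, 10), rtol=1e-9,
        )

    def test_bound_mode_is_quadrature_sum(self, front_head_sim):
        # per-axis noise 4 nm in the bound state -> 2D s.d. ~ 4*sqrt(2)
        traj, truth = front_head_sim
        sd = compute_rolling_sd(traj, 20)
        bound_sd = sd[(truth.labels == BOUND) & np.isfinite(sd)]
        hist, edges = np.histogram(bound_sd, bins=200)
        mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert mode == pytest.approx(4 * math.sqrt(2), rel=0.05)

    def test_too_short_rejected(self):
        traj = Trajectory2D.from_positions(np.zeros(30), np.zeros(30), 1e3)
        with pytest.raises(InvalidInputError):
            compute_rolling_sd(traj, half_window=20)


class TestNoiseFloor:
    def test_gaussian_samples_recovered(self):
        rng = np.random.default_rng(1)
        sd = rng.normal(5.0, 1.0, 50_000)
        floor = fit_noise_floor(sd)
        assert floor.mu == pytest.approx(5.0, rel=0.05)
        assert floor.sigma == pytest.approx(1.0, rel=0.05)
        assert floor.threshold == pytest.approx(9.0, rel=0.05)

    def test_degenerate_histogram(self):
        with pytest.warns(UserWarning, match="degenerate"):
            floor = fit_noise_floor(np.full(2000, 5.0))
        assert floor.degenerate
        assert floor.mu == 5.0 and floor.sigma == 0.0 and floor.threshold == 5.0

    def test_too_few_values(self):
        with pytest.raises(InvalidInputError):
            fit_noise_floor(np.random.default_rng(0).normal(5, 1, 500))

    def test_bimodal_fit_tracks_primary_mode(self, front_head_sim):
        # oracle: the simulator's bound-state noise (4 nm/axis -> 5.66 nm 2D)
        traj, _ = front_head_sim
        sd = compute_rolling_sd(traj, 20)
        floor = fit_noise_floor(sd)
        assert floor.mu == pytest.approx(4 * math.sqrt(2), rel=0.05)
        # global mean is dragged up by the unbound tail; the fit must not be
        assert floor.mu < np.nanmean(sd)


class TestDetectTransitions:
    floor = NoiseFloor(mu=5.0, sigma=1.0, threshold=9.0)

    def test_all_below_threshold(self):
        sd = np.full(100, 5.0)
        initial, trans = detect_transitions(sd, self.floor, persistence=10)
        assert initial == "bound"
        assert trans == []

    def test_square_excursion_detected(self):
        sd = np.full(200, 5.0)
        sd[80:95] = 12.0  # 15 frames above
        initial, trans = detect_transitions(sd, self.floor, persistence=10)
        assert initial == "bound"
        assert trans == [(80, "bound_to_unbound"), (95, "unbound_to_bound")]

    def test_short_excursion_ignored(self):
        sd = np.full(200, 5.0)
        sd[80:89] = 12.0  # 9 frames < persistence 10
        _, trans = detect_transitions(sd, self.floor, persistence=10)
        assert trans == []

    def test_starts_unbound_when_first_frame_above(self):
        sd = np.full(100, 12.0)
        sd[50:] = 5.0
        initial, trans = detect_transitions(sd, self.floor, persistence=10)
        assert initial == "unbound"
        assert trans == [(50, "unbound_to_bound")]

    def test_nan_edges_ignored(self):
        sd = np.full(120, 5.0)
        sd[:20] = np.nan
        sd[-20:] = np.nan
        sd[50:70] = 12.0
        _, trans = detect_transitions(sd, self.floor, persistence=10)
        assert trans == [(50, "bound_to_unbound"), (70, "unbound_to_bound")]


class TestStepRefinement:
    def test_noiseless_step_found_exactly(self):
        traj = make_step_trajectory(200, step_frame=100, step_on=-8.0)
        assert refine_transition_stepfit(traj, 105, 40) == 100
        assert refine_transition_stepfit(traj, 95, 40) == 100

    def test_flat_signal_returns_approx(self):
        traj = Trajectory2D.from_positions(np.zeros(200), np.zeros(200), 2e4)
        assert refine_transition_stepfit(traj, 90, 40) == 90

    def test_out_of_bounds_window_clipped(self):
        traj = make_step_trajectory(100, step_frame=30, step_on=-8.0)
        with pytest.warns(UserWarning, match="clipped"):
            assert refine_transition_stepfit(traj, 10, 40) == 30

    def test_noisy_step_recovery_monte_carlo(self):
        # >= 95% of replicates within +/- 2 frames of the true step
        hits = 0
        for seed in range(500):
            traj = make_step_trajectory(160, step_frame=80, step_on=-8.0,
                                        noise=3.0, seed=seed)
            approx = 80 + int(np.random.default_rng(seed ^ 0xABC).integers(-5, 6))
            if abs(refine_transition_stepfit(traj, approx, 40) - 80) <= 2:
                hits += 1
        assert hits >= 475


class TestMergeRule:
    frame_rate = 1000.0

    def _make(self, gap_frames, mid_offset):
        # bound(100) U(30) bound(gap) U(30) bound(100); unbound offset -8
        n = 260 + gap_frames
        labels = np.full(n, BOUND, np.int8)
        labels[100:130] = UNBOUND
        labels[130 + gap_frames:160 + gap_frames] = UNBOUND
        on = np.zeros(n)
        on[labels == UNBOUND] = -8.0
        on[130:130 + gap_frames] = mid_offset
        traj = Trajectory2D.from_positions(on, np.zeros(n), self.frame_rate)
        seg = seg_from_labels(labels, self.frame_rate, traj)
        return seg, traj

    def test_close_displaced_triplet_merged(self):
        seg, traj = self._make(gap_frames=30, mid_offset=-8.0)  # 30 ms < 50 ms
        merged = apply_g0_merge_rule(seg, traj, merge_gap=0.050)
        assert len(merged.merged_groups) == 1
        unbound = [d for d in merged.dwells if d.state == "unbound"]
        assert len(unbound) == 1
        assert unbound[0].start_frame == 100 and unbound[0].end_frame == 190

    def test_wide_gap_not_merged(self):
        seg, traj = self._make(gap_frames=80, mid_offset=-8.0)  # 80 ms
        merged = apply_g0_merge_rule(seg, traj, merge_gap=0.050)
        assert merged.merged_groups == []
        assert sum(d.state == "unbound" for d in merged.dwells) == 2

    def test_undisplaced_intervening_bound_not_merged(self):
        seg, traj = self._make(gap_frames=30, mid_offset=0.0)
        merged = apply_g0_merge_rule(seg, traj, merge_gap=0.050)
        assert merged.merged_groups == []
        assert sum(d.state == "unbound" for d in merged.dwells) == 2


class TestExtractDwells:
    def test_hand_counted_labels(self):
        labels = [BOUND, BOUND, BOUND, UNBOUND, UNBOUND, BOUND]
        seg = seg_from_labels(labels, 1000.0)
        df = extract_dwells(seg)
        assert list(df.state) == ["bound", "unbound", "bound"]
        np.testing.assert_allclose(df.duration_s, [0.003, 0.002, 0.001])
        assert list(df.censored) == [True, False, True]

    def test_single_state_trace(self):
        seg = seg_from_labels([BOUND] * 50, 1000.0)
        df = extract_dwells(seg)
        assert len(df) == 1
        assert bool(df.censored.iloc[0])

    def test_edge_frames_excluded(self):
        labels = [EDGE_UNDEFINED] * 3 + [BOUND] * 10 + [EDGE_UNDEFINED] * 3
        seg = seg_from_labels(labels, 1000.0)
        df = extract_dwells(seg)
        assert len(df) == 1
        assert df.start_frame.iloc[0] == 3 and df.end_frame.iloc[0] == 13

    def test_recovery_against_ground_truth(self, front_head_sim, front_head_params):
        traj, truth = front_head_sim
        seg = segment_trajectory(traj)
        df = extract_dwells(seg)
        rec = df[(df.state == "bound") & ~df.censored].duration_s.mean()
        assert rec == pytest.approx(front_head_params.mean_bound_dwell, rel=0.10)


class TestClassifyOrigin:
    def test_backward_displacement_is_leading(self):
        labels = [BOUND] * 50 + [UNBOUND] * 30 + [BOUND] * 50
        on = np.zeros(130)
        on[50:80] = -8.0
        traj = Trajectory2D.from_positions(on, np.zeros(130), 1000.0)
        seg = seg_from_labels(labels, 1000.0, traj)
        classify_detachment_origin(traj, seg)
        assert [d.origin for d in seg.dwells if d.state == "unbound"] == ["leading"]

    def test_forward_displacement_is_trailing(self):
        labels = [BOUND] * 50 + [UNBOUND] * 30 + [BOUND] * 50
        on = np.zeros(130)
        on[50:80] = 8.0
        traj = Trajectory2D.from_positions(on, np.zeros(130), 1000.0)
        seg = seg_from_labels(labels, 1000.0, traj)
        classify_detachment_origin(traj, seg)
        assert [d.origin for d in seg.dwells if d.state == "unbound"] == ["trailing"]

    def test_first_dwell_unlabeled(self):
        labels = [UNBOUND] * 30 + [BOUND] * 50
        on = np.zeros(80)
        traj = Trajectory2D.from_positions(on, np.zeros(80), 1000.0)
        seg = seg_from_labels(labels, 1000.0, traj)
        out = classify_detachment_origin(traj, seg)
        assert out[0] is None

    def test_simulated_offset_mostly_leading(self, front_head_sim):
        traj, _ = front_head_sim
        seg = segment_trajectory(traj)  # unbound offset is -8 nm
        origins = [d.origin for d in seg.dwells
                   if d.state == "unbound" and d.origin is not None]
        assert len(origins) > 50
        assert np.mean([o == "leading" for o in origins]) >= 0.90


class TestMedianFilter:
    def test_constant_unchanged(self):
        traj = Trajectory2D.from_positions(np.full(100, 2.0), np.full(100, -3.0),
                                           1e3)
        sm = median_filter_trace(traj, window=51)
        np.testing.assert_array_equal(sm.on_axis, traj.on_axis)
        np.testing.assert_array_equal(sm.off_axis, traj.off_axis)

    def test_single_outlier_removed(self):
        on = np.zeros(100)
        on[50] = 100.0
        traj = Trajectory2D.from_positions(on, np.zeros(100), 1e3)
        sm = median_filter_trace(traj, window=51)
        np.testing.assert_allclose(sm.on_axis, 0.0, atol=1e-12)

    def test_ramp_preserved_interior(self):
        on = np.arange(200, dtype=float)
        traj = Trajectory2D.from_positions(on, np.zeros(200), 1e3)
        sm = median_filter_trace(traj, window=51)
        # brute-force oracle: median of each full symmetric window
        for i in range(25, 175):
            assert sm.on_axis[i] == np.median(on[i - 25:i + 26])

    def test_even_window_rejected(self):
        traj = Trajectory2D.from_positions(np.zeros(100), np.zeros(100), 1e3)
        with pytest.raises(InvalidParameterError):
            median_filter_trace(traj, window=50)

    def test_segment_boundaries_respected(self):
        # filtering per dwell: the unbound level must not bleed into bound
        labels = [BOUND] * 60 + [UNBOUND] * 60 + [BOUND] * 60
        on = np.where(np.array(labels) == UNBOUND, -8.0, 0.0)
        traj = Trajectory2D.from_positions(on, np.zeros(180), 1e3)
        seg = seg_from_labels(labels, 1e3, traj)
        sm = median_filter_trace(traj, seg, window=51)
        np.testing.assert_array_equal(sm.on_axis, on)


class TestPipelineProperties:
    def test_label_agreement(self, front_head_sim):
        traj, truth = front_head_sim
        seg = segment_trajectory(traj)
        defined = seg.labels != EDGE_UNDEFINED
        agreement = np.mean(seg.labels[defined] == truth.labels[defined])
        assert agreement >= 0.97

    def test_segmentation_invariants_hold(self, front_head_sim):
        traj, _ = front_head_sim
        seg = segment_trajectory(traj)
        seg.validate()

    def test_idempotence_on_reemitted_trajectory(self, front_head_sim, tmp_path):
        from motorkin.io import read_trajectory_csv, write_trajectory_csv

        traj, _ = front_head_sim
        seg1 = segment_trajectory(traj)
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        seg2 = segment_trajectory(read_trajectory_csv(path, traj.frame_rate))
        np.testing.assert_array_equal(seg1.labels, seg2.labels)

    def test_threshold_monotonicity(self, front_head_sim):
        traj, _ = front_head_sim
        counts = []
        for k in (3.0, 4.0, 5.0, 6.0):
            seg = segment_trajectory(
                traj, SegmentationParams(threshold_multiplier=k), merge=False,
                classify_origin=False,
            )
            counts.append(sum(d.state == "unbound" for d in seg.dwells))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_unbound_dwell_recovery(self, front_head_sim, front_head_params):
        traj, _ = front_head_sim
        df = extract_dwells(segment_trajectory(traj))
        rec = df[(df.state == "unbound") & ~df.censored].duration_s.mean()
        assert rec == pytest.approx(front_head_params.mean_unbound_dwell, rel=0.15)
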