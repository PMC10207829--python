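import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import echotrack as et
from echotrack.corrections import sigmoid_value


def linear_drift_tracker(truth, slope_xy):
    """Deterministic tracker drifting by a fixed vector per frame."""
    return et.make_drifting_tracker(truth, bias_px_per_frame=slope_xy)


class TestFitSigmoid:
    def test_closed_form_steepness(self):
        params = et.fit_sigmoid(d=10.0, T=100, epsilon=0.01)
        assert params.A == 10.0
        assert params.B == pytest.approx(2 * math.log(99) / 100)  # ~0.09190
        assert params.B == pytest.approx(0.09190, abs=5e-6)
        assert params.C == 50.0 and params.D == 0.0

    def test_boundary_values(self):
        d, T, eps = 7.0, 80, 0.02
        params = et.fit_sigmoid(d, T, eps)
        assert sigmoid_value(params, 0) == pytest.approx(eps * d)
        assert sigmoid_value(params, T) == pytest.approx((1 - eps) * d)
        assert sigmoid_value(params, T / 2) == pytest.approx(d / 2)

    def test_zero_drift_gives_zero_curve(self):
        params = et.fit_sigmoid(0.0, 50)
        j = np.arange(51)
        np.testing.assert_array_equal(sigmoid_value(params, j), 0.0)

    @pytest.mark.parametrize("eps", [0.0, 0.5, 0.9, -0.1])
    def test_epsilon_domain_enforced(self, eps):
        with pytest.raises(ValueError):
            et.fit_sigmoid(1.0, 10, eps)

    @settings(deadline=None, derandomize=True)
    @given(
        d=st.floats(-50, 50),
        T=st.integers(2, 2000),
        eps=st.floats(0.001, 0.49),
    )
    def test_boundaries_hold_for_all_parameters(self, d, T, eps):
        params = et.fit_sigmoid(d, T, eps)
        assert sigmoid_value(params, 0) == pytest.approx(eps * d, abs=1e-9)
        assert sigmoid_value(params, T) == pytest.approx((1 - eps) * d, abs=1e-9)


class TestSelectCorrectionFrames:
    @pytest.mark.parametrize(
        "k,ordinals",
        [(0, ()), (1, (4,)), (2, (3, 6)), (3, (2, 4, 6)), (4, (1, 3, 5, 7))],
    )
    def test_standard_eight_label_design(self, labels8, k, ordinals):
        sched = et.select_correction_frames(labels8, k)
        expected = tuple(labels8.frames[o - 1] for o in ordinals)
        assert sched.frames == expected

    def test_nonstandard_inputs_need_explicit_flag(self, labels8, reach_truth):
        labels5 = et.make_labelset(reach_truth, 5)
        with pytest.raises(ValueError):
            et.select_correction_frames(labels5, 2)
        with pytest.raises(ValueError):
            et.select_correction_frames(labels8, 5)
        sched = et.select_correction_frames(labels5, 2, allow_generic=True)
        assert len(sched) == 2

    def test_schedule_must_increase(self):
        with pytest.raises(ValueError):
            et.CorrectionSchedule([5, 5])


class TestSTC:
    def test_exact_tracker_is_identity(self, reach_truth, blank_video, labels8):
        tracker = et.make_drifting_tracker(reach_truth)  # ideal: zero drift
        raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
        sched = et.select_correction_frames(labels8, 2)
        out = et.apply_stc(raw, labels8, sched, 0.01, blank_video, tracker)
        np.testing.assert_allclose(out.positions, raw.positions, atol=1e-9)

    def test_linear_drift_residual_is_epsilon_fraction(
        self, reach_truth, blank_video, labels8
    ):
        """20 px of accumulated drift leaves a 0.2 px residual at eps=0.01."""
        sched = et.select_correction_frames(labels8, 1)
        f = sched.frames[0]
        slope = 20.0 / f  # drift reaches 20 px at the correction frame
        tracker = linear_drift_tracker(reach_truth, (slope, 0.0))
        raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
        out = et.apply_stc(raw, labels8, sched, 0.01, blank_video, tracker)
        resid = np.linalg.norm(out.at(f) - labels8[f], axis=1)
        np.testing.assert_allclose(resid, 0.01 * 20.0, rtol=1e-9)

    def test_mean_error_non_increasing_in_k(self, reach_truth, blank_video, labels8):
        tracker = et.make_drifting_tracker(
            reach_truth, bias_px_per_frame=(0.02, 0.01), random_walk_sigma=0.05, seed=0
        )
        raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
        means = []
        for k in range(5):
            sched = et.select_correction_frames(labels8, k)
            out = et.apply_stc(raw, labels8, sched, 0.01, blank_video, tracker)
            means.append(et.error_at_labels(out, labels8).mean_error_px)
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))

    def test_empty_schedule_is_identity_over_scheduling(
        self, reach_truth, blank_video, labels8
    ):
        tracker = linear_drift_tracker(reach_truth, (0.01, 0.0))
        raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
        out = et.apply_stc(
            raw, labels8, et.CorrectionSchedule([]), 0.01, blank_video, tracker
        )
        np.testing.assert_allclose(out.positions, raw.positions)

    def test_unlabeled_schedule_frame_fails_before_tracking(
        self, reach_truth, blank_video, labels8
    ):
        tracker = et.make_drifting_tracker(reach_truth)
        raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
        with pytest.raises(ValueError, match="not labeled"):
            et.apply_stc(
                raw, labels8, et.CorrectionSchedule([123]), 0.01, blank_video, tracker
            )


class TestRTC:
    def _traj(self, arr):
        return et.Trajectory(np.asarray(arr, dtype=float))

    def test_idempotent_on_equal_paths(self):
        p = self._traj(np.random.default_rng(0).uniform(0, 10, (20, 2, 2)))
        out = et.apply_rtc(p, p.copy())
        np.testing.assert_array_equal(out.positions, p.positions)

    def test_arithmetic_mean(self):
        a = self._traj(np.zeros((10, 1, 2)))
        b = self._traj(np.full((10, 1, 2), 10.0))
        out = et.apply_rtc(a, b)
        np.testing.assert_array_equal(out.positions, np.full((10, 1, 2), 5.0))

    def test_linear_drift_halved_at_both_ends(self):
        """Opposite end-point drifts of d average to d/2 errors at each end."""
        n, d = 101, 8.0
        truth = np.zeros((n, 1, 2))
        ramp = np.linspace(0.0, d, n)
        p_f = self._traj(truth + ramp[:, None, None] * [[1.0, 0.0]])
        p_b = self._traj(truth - ramp[::-1, None, None] * [[1.0, 0.0]])
        out = et.apply_rtc(p_f, p_b)
        assert abs(out.positions[0, 0, 0]) == pytest.approx(d / 2)
        assert abs(out.positions[-1, 0, 0]) == pytest.approx(d / 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            et.apply_rtc(self._traj(np.zeros((5, 1, 2))), self._traj(np.zeros((6, 1, 2))))

    def test_validity_conjunction(self):
        a = et.Trajectory(np.zeros((4, 1, 2)), np.array([[1], [1], [0], [1]], bool))
        b = et.Trajectory(np.zeros((4, 1, 2)), np.array([[1], [0], [1], [1]], bool))
        out = et.apply_rtc(a, b)
        np.testing.assert_array_equal(out.valid.ravel(), [True, False, False, True])


class TestRSTC:
    @settings(deadline=None, derandomize=True)
    @given(
        t_i=st.integers(0, 500),
        span=st.integers(2, 2000),
        eps=st.floats(0.001, 0.49),
    )
    def test_weights_always_sum_to_one(self, t_i, span, eps):
        w_f, w_b = et.rstc_weights(et.SegmentBounds(t_i, t_i + span), eps)
        np.testing.assert_allclose(w_f + w_b, 1.0, atol=1e-12)

    def test_weight_boundary_values(self):
        w_f, _ = et.rstc_weights(et.SegmentBounds(0, 100), 0.01)
        assert w_f[0] == pytest.approx(0.99)
        assert w_f[-1] == pytest.approx(0.01)

    def test_equal_paths_unchanged(self):
        p = et.Trajectory(np.random.default_rng(1).uniform(0, 5, (30, 2, 2)))
        out = et.apply_rstc(p, p.copy())
        np.testing.assert_allclose(out.positions, p.positions, atol=1e-12)

    def test_midpoint_equals_rtc(self):
        rng = np.random.default_rng(2)
        p_f = et.Trajectory(rng.uniform(0, 5, (101, 1, 2)))
        p_b = et.Trajectory(rng.uniform(0, 5, (101, 1, 2)))
        rstc = et.apply_rstc(p_f, p_b)
        rtc = et.apply_rtc(p_f, p_b)
        np.testing.assert_allclose(rstc.positions[50], rtc.positions[50], atol=1e-12)

    def test_forward_drift_suppressed_at_end(self):
        """A forward path 20 px off at the end contributes only eps there."""
        n, drift = 101, 20.0
        truth = np.zeros((n, 1, 2))
        ramp = np.linspace(0.0, drift, n)
        p_f = et.Trajectory(truth + ramp[:, None, None] * [[1.0, 0.0]])
        p_b = et.Trajectory(truth.copy())
        out = et.apply_rstc(p_f, p_b, epsilon=0.01)
        assert abs(out.positions[-1, 0, 0]) <= 0.01 * drift + 1e-9


class TestSegmentwiseRSTC:
    def test_ideal_tracker_pins_labels(self, reach_truth, blank_video, labels8):
        tracker = et.make_drifting_tracker(reach_truth)
        sched = et.select_correction_frames(labels8, 4)
        out = et.apply_segmentwise_rstc(blank_video, labels8, sched, tracker)
        for f in labels8.frames:
            np.testing.assert_allclose(out.at(f), labels8[f], atol=1e-12)

    def test_single_segment_reduces_to_rstc(self, reach_truth, blank_video):
        labels2 = et.make_labelset(reach_truth, 2)
        tracker = et.make_drifting_tracker(reach_truth, random_walk_sigma=0.1, seed=3)
        out = et.apply_segmentwise_rstc(
            blank_video, labels2, et.CorrectionSchedule([]), tracker
        )
        p_f = et.track_forward(blank_video, labels2[0], 0, 1600, tracker)
        p_b = et.track_backward(blank_video, labels2[1600], 0, 1600, tracker)
        blended = et.apply_rstc(p_f, p_b)
        # interior frames follow the RSTC blend of *some* pair of passes;
        # boundaries are pinned exactly
        np.testing.assert_allclose(out.at(0), labels2[0])
        np.testing.assert_allclose(out.at(1600), labels2[1600])
        assert out.n_frames == blended.n_frames

    def test_beats_stc_on_random_walk_drift(self, reach_truth, blank_video, labels8):
        """Bidirectional blending outperforms one-directional STC on average."""
        sched = et.select_correction_frames(labels8, 4)
        stc_err, both_err = [], []
        for seed in range(10):
            tracker = et.make_drifting_tracker(
                reach_truth, random_walk_sigma=0.15, seed=seed
            )
            raw = et.track_forward(blank_video, labels8[0], 0, 1600, tracker)
            stc = et.apply_stc(raw, labels8, sched, 0.01, blank_video, tracker)
            both = et.apply_segmentwise_rstc(blank_video, labels8, sched, tracker)
            stc_err.append(et.error_at_labels(stc, labels8).mean_error_px)
            both_err.append(et.error_at_labels(both, labels8).mean_error_px)
        assert np.mean(both_err) < np.mean(stc_err)


class TestPseudoLabels:
    def test_stride_200_over_1000_frames(self):
        traj = et.Trajectory(np.zeros((1000, 1, 2)))
        labels = et.pseudo_label_schedule(traj, 200)
        assert labels.frames == [0, 200, 400, 600, 800, 999]

    def test_large_stride_keeps_endpoints(self):
        traj = et.Trajectory(np.zeros((50, 1, 2)))
        labels = et.pseudo_label_schedule(traj, 1000)
        assert labels.frames == [0, 49]

    def test_invalid_frames_skipped(self):
        valid = np.ones((1000, 1), bool)
        valid[400] = False
        traj = et.Trajectory(np.zeros((1000, 1, 2)), valid)
        labels = et.pseudo_label_schedule(traj, 200)
        assert 400 not in labels.frames

    def test_ground_truth_pseudo_labels_pin_sampled_frames(
        self, reach_truth, blank_video
    ):
        pseudo = et.pseudo_label_schedule(reach_truth, 200)
        tracker = et.make_drifting_tracker(reach_truth, random_walk_sigma=0.1, seed=5)
        out = et.apply_segmentwise_rstc(
            blank_video, pseudo, et.CorrectionSchedule(pseudo.frames[1:-1]), tracker
        )
        for f in pseudo.frames:
            np.testing.assert_allclose(out.at(f), reach_truth.at(f), atol=1e-12)
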