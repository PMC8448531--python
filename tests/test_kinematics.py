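import numpy as np
import pytest

from chickgait import kinematics as kin, simulate as sim
from chickgait.errors import (
    InsufficientDataError,
    NoGaitError,
    ResolutionError,
    ValidationError,
)
from conftest import make_sequence, make_stride


class TestEventDetection:
    def test_recovers_true_events_noise_free(self, clean_gait):
        seqs, events, _ = clean_gait
        det = kin.detect_gait_events(seqs["side"])
        fps = seqs["side"].fps
        for leg in ("left", "right"):
            assert len(det.toe_off[leg]) == len(events.toe_off[leg])
            err = np.abs(det.toe_off[leg] - events.toe_off[leg]) * fps
            assert err.max() <= 1.0 + 1e-6
            err = np.abs(det.foot_contact[leg] - events.foot_contact[leg]) * fps
            assert err.max() <= 1.0 + 1e-6

    def test_flat_trajectory_is_no_gait(self):
        n = 200
        seq = make_sequence({("right", "toe"): np.column_stack(
            [np.arange(n, dtype=float), np.zeros(n)]
        )})
        with pytest.raises(NoGaitError):
            kin.detect_gait_events(seq)

    def test_single_stride_is_insufficient(self):
        # one swing bump only -> a single toe-off
        t = np.linspace(0, 1, 240)
        y = np.where((t > 0.4) & (t < 0.6), 1.0, 0.0)
        seq = make_sequence({("right", "toe"): np.column_stack([t, y])})
        with pytest.raises(InsufficientDataError):
            kin.detect_gait_events(seq)

    def test_noisy_recovery_within_two_frames(self):
        """Monte-Carlo: >= 95 % of events within 2 frames at 0.05 cm jitter."""
        ok = tot = 0
        for seed in range(20):
            p = sim.GaitParams(n_strides=10, noise_sd=0.05, seed=seed)
            seqs, events, _ = sim.generate_gait(p)
            det = kin.detect_gait_events(seqs["side"])
            for leg in ("left", "right"):
                for true_times, det_times in (
                    (events.toe_off[leg], det.toe_off[leg]),
                    (events.foot_contact[leg], det.foot_contact[leg]),
                ):
                    for t in true_times:
                        err = np.min(np.abs(det_times - t)) * p.fps
                        tot += 1
                        ok += err <= 2.0 + 1e-6
        assert ok / tot >= 0.95


class TestStrideSegmentation:
    def test_k_toe_offs_give_k_minus_1_strides(self, clean_gait):
        seqs, events, _ = clean_gait
        strides = kin.segment_strides(seqs["side"], events)
        for leg in ("left", "right"):
            n_to = len(events.toe_off[leg])
            assert sum(s.leg == leg for s in strides) == n_to - 1

    def test_constant_stance_baseline(self):
        stride = make_stride(np.full(100, 3.0))
        assert stride.stance_baseline == pytest.approx(3.0)

    def test_baseline_matches_generator(self, clean_gait):
        seqs, events, _ = clean_gait
        strides = kin.segment_strides(seqs["side"], events)
        for s in strides:
            assert s.stance_baseline == pytest.approx(3.0, abs=1e-9)

    def test_missing_knee_frames_flagged_not_dropped(self, clean_gait):
        seqs, events, _ = clean_gait
        seq = seqs["side"]
        data = seq.data.copy()
        data.loc[10, ("right", "knee", "y")] = np.nan
        seq2 = kin.TrackedSequence.__new__(kin.TrackedSequence)
        import dataclasses

        seq2 = dataclasses.replace(seq, data=data)
        strides = kin.segment_strides(seq2, events)
        assert sum(s.has_missing for s in strides) >= 0  # no exception
        assert len(strides) == len(kin.segment_strides(seq, events))


class TestPhase:
    @pytest.mark.parametrize(
        "left, r1, r2, expected",
        [
            (0.25, 0.0, 0.5, 180.0),  # midpoint -> perfect alternation
            (0.0, 0.0, 0.5, 0.0),
            (0.45, 0.0, 0.6, 270.0),
        ],
    )
    def test_formula_values(self, left, r1, r2, expected):
        assert kin.compute_lr_phase(left, r1, r2) == pytest.approx(expected)

    def test_out_of_cycle_rejected(self):
        with pytest.raises(ValidationError):
            kin.compute_lr_phase(0.7, 0.0, 0.5)

    def test_shift_and_rescale_invariance(self):
        base = kin.compute_lr_phase(0.3, 0.1, 0.6)
        shifted = kin.compute_lr_phase(0.3 + 5, 0.1 + 5, 0.6 + 5)
        scaled = kin.compute_lr_phase(0.3 * 3, 0.1 * 3, 0.6 * 3)
        assert shifted == pytest.approx(base)
        assert scaled == pytest.approx(base)


class TestSwingNormalization:
    def test_linear_ramp_range(self):
        stride = make_stride(np.linspace(2, 4, 100), swing_frac=1.0)
        prof = kin.normalize_swing(stride)
        assert prof.range == pytest.approx(2.0, abs=1e-6)

    def test_constant_range_zero(self):
        stride = make_stride(np.full(100, 3.0))
        assert kin.normalize_swing(stride).range == pytest.approx(0.0)

    def test_time_dilation_invariance(self):
        # same samples on a doubled time base -> identical profile
        shape = 3.0 + np.sin(np.linspace(0, np.pi, 41))
        fast = make_stride(shape, fps=240.0, swing_frac=1.0)
        slow = make_stride(shape, fps=120.0, swing_frac=1.0)
        np.testing.assert_allclose(
            kin.normalize_swing(fast).values, kin.normalize_swing(slow).values,
            atol=1e-6,
        )

    def test_too_few_swing_frames(self):
        stride = make_stride(np.ones(10), swing_frac=0.2)
        with pytest.raises(ResolutionError):
            kin.normalize_swing(stride)


class TestJointAngle:
    def _angle(self, ankle, tmp, toe):
        seq = make_sequence({
            ("right", "ankle"): [ankle], ("right", "tmp"): [tmp],
            ("right", "toe"): [toe],
        })
        return kin.joint_angle_series(seq, "ankle", "tmp", "toe")[0]

    def test_collinear_is_straight(self):
        assert self._angle((0, 2), (0, 1), (0, 0)) == pytest.approx(180.0)

    def test_perpendicular(self):
        assert self._angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)

    def test_interior_angle_geometry(self):
        # vertex at origin: ankle up, toe up-forward -> 45 degrees between them
        assert self._angle((0, 1), (0, 0), (1, 1)) == pytest.approx(45.0)

    def test_coincident_vertex_is_nan(self):
        assert np.isnan(self._angle((0, 0), (0, 0), (1, 1)))

    def test_generator_excursion_recovered(self, clean_gait):
        seqs, events, labels = clean_gait
        strides = kin.segment_strides(seqs["side"], events)
        right = [s for s in strides if s.leg == "right"]
        for s in right:
            prof = kin.normalize_swing(s, "tmp_angle")
            assert prof.range == pytest.approx(50.0, abs=0.5)


class TestCollapseDetector:
    def test_below_threshold_is_collapse(self):
        knee = np.full(100, 3.0)
        knee[80] = 2.4  # 0.80 of the 3.0 stance baseline
        stride = make_stride(knee, swing_frac=0.4)
        stride.knee_height[:40] = 3.0  # keep stance mean at 3.0
        (score,) = kin.detect_collapses([stride])
        assert score.collapse
        assert score.collapse_fraction == pytest.approx(0.8, abs=0.01)
        assert score.collapse_frame == 80

    def test_boundary_is_strictly_below(self):
        knee = np.full(100, 3.0)
        knee[80] = 2.55  # exactly 85 %
        (score,) = kin.detect_collapses([make_stride(knee)])
        assert not score.collapse

    def test_constant_trace_no_collapse(self):
        (score,) = kin.detect_collapses([make_stride(np.full(60, 3.0))])
        assert not score.collapse

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            kin.detect_collapses([make_stride(np.zeros(60))])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        strides = []
        for _ in range(200):
            knee = 3.0 + rng.normal(0, 0.4, 80)
            strides.append(make_stride(np.abs(knee) + 0.5))
        scores = kin.detect_collapses(strides, 0.85)
        for stride, score in zip(strides, scores):
            baseline = np.mean(stride.knee_height[stride.stance_mask])
            expected = any(v < 0.85 * baseline for v in stride.knee_height)
            assert score.collapse == expected


class TestOvershootDetector:
    def _strides(self, peaks):
        out = []
        for pk in peaks:
            knee = np.full(100, 3.0)
            knee[10:30] = np.linspace(3.0, pk, 20)
            out.append(make_stride(knee, swing_frac=0.4))
        return out

    def test_high_peak_is_overshoot(self):
        strides = self._strides([5.0, 5.0, 5.0, 5.0, 7.0])
        scores = kin.detect_overshoots(strides)
        # reference = mean(5,5,5,5,7) = 5.4; 7/5.4 = 1.296 > 1.15
        assert scores[4].overshoot
        assert not any(s.overshoot for s in scores[:4])

    def test_boundary_is_strictly_above(self):
        strides = self._strides([5.0, 5.0, 5.75])
        scores = kin.detect_overshoots(strides, overshoot_threshold_fraction=1.15)
        ref = np.mean([5.0, 5.0, 5.75])
        assert scores[2].overshoot == (5.75 / ref > 1.15)

    def test_identical_strides_no_overshoot(self):
        scores = kin.detect_overshoots(self._strides([5.0] * 6))
        assert not any(s.overshoot for s in scores)

    def test_needs_three_strides(self):
        with pytest.raises(InsufficientDataError):
            kin.detect_overshoots(self._strides([5.0, 5.0]))


class TestCollapseContext:
    def _scores(self, collapses, overshoots, n=12):
        scores = [kin.StepScore(stride_id=i, leg="right") for i in range(n)]
        for i in collapses:
            scores[i].collapse = True
        for i in overshoots:
            scores[i].overshoot = True
        return scores

    def test_followed(self):
        scores = self._scores({5}, {6})
        props = kin.classify_collapse_context(scores)
        assert scores[5].collapse_context == "followed_by_overshoot"
        assert props["followed_by_overshoot"] == 1.0

    def test_isolated(self):
        props = kin.classify_collapse_context(self._scores({5}, set()))
        assert props["isolated"] == 1.0

    def test_mixed_proportions(self):
        props = kin.classify_collapse_context(self._scores({2, 8}, {1, 9}))
        assert props == {
            "isolated": 0.0,
            "followed_by_overshoot": 0.5,
            "preceded_by_overshoot": 0.5,
        }

    def test_tie_goes_to_followed(self):
        scores = self._scores({5}, {4, 6})
        kin.classify_collapse_context(scores)
        assert scores[5].collapse_context == "followed_by_overshoot"


class TestLandingAngleAndWidthAndVelocity:
    @pytest.mark.parametrize(
        "knee, tmp, expected",
        [((0, 1), (1, 0), 45.0), ((0, 1), (0, 0), 90.0), ((0, np.sqrt(3)), (1, 0), 60.0)],
    )
    def test_landing_angles(self, knee, tmp, expected):
        assert kin.landing_angle(np.array(knee), np.array(tmp)) == pytest.approx(expected)

    def test_knee_below_tmp_warns_signed(self):
        with pytest.warns(UserWarning):
            angle = kin.landing_angle(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert angle < 0

    def test_stride_width_constant_separation(self, clean_gait):
        seqs, events, _ = clean_gait
        widths = kin.stride_width(seqs["top"], events)
        assert len(widths) > 0
        np.testing.assert_allclose(widths, 4.2, atol=1e-9)

    def test_coincident_feet_zero_width(self, clean_gait):
        seqs, events, _ = clean_gait
        seq = seqs["top"]
        import dataclasses

        data = seq.data.copy()
        data[("left", "toe", "y")] = data[("right", "toe", "y")]
        widths = kin.stride_width(dataclasses.replace(seq, data=data), events)
        np.testing.assert_allclose(widths, 0.0, atol=1e-9)

    def test_swing_velocity_examples(self):
        stride = make_stride(np.full(48, 3.0), swing_frac=1.0,
                             toe_x=np.linspace(0, 10, 48))
        stride.t_foot_contact = 0.2
        stride.times = np.linspace(0, 0.2, 48, endpoint=False)
        assert kin.swing_velocity(stride) == pytest.approx(50.0, rel=0.05)

    def test_swing_velocity_matches_generator(self, clean_gait):
        seqs, events, _ = clean_gait
        strides = kin.segment_strides(seqs["side"], events)
        for s in strides:
            # 10 cm advance over a 0.2 s swing
            assert kin.swing_velocity(s) == pytest.approx(50.0, rel=0.05)

    def test_zero_duration_swing_rejected(self):
        stride = make_stride(np.ones(20), toe_x=np.zeros(20))
        stride.t_foot_contact = stride.t_toe_off
        with pytest.raises(ValidationError):
            kin.swing_velocity(stride)


class TestScoreSteps:
    def test_noise_free_scores_clean(self, clean_gait):
        seqs, events, _ = clean_gait
        scores, widths = kin.score_steps(seqs["side"], events, seq_top=seqs["top"])
        assert not scores["collapse"].any()
        assert not scores["overshoot"].any()
        right = scores[scores["leg"] == "right"]
        np.testing.assert_allclose(right["lr_phase"].dropna(), 180.0, atol=0.01)
        np.testing.assert_allclose(scores["knee_range"], 2.0, atol=0.05)
        np.testing.assert_allclose(scores["tmp_range"], 50.0, atol=0.5)
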