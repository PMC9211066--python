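"""Posterior smoothing, state-transition gating, threshold search, FN rate."""

import numpy as np
import pytest

from graspdecode.decision import (
    DEFAULT_GRID,
    SmoothedSequence,
    TransitionConfig,
    false_negative_rate,
    gate,
    optimize_thresholds,
    smooth,
    smooth_labels,
)
from graspdecode.gru import PosteriorSequence


def random_simplex(rng, n, concentration=1.0):
    frames = rng.dirichlet(np.full(7, concentration), size=n)
    return frames


def brute_force_gate(frames, w_gg, w_gr):
    """Independent per-step simulation of the transition rules."""
    out = []
    for t, frame in enumerate(frames):
        y = int(np.argmax(frame))
        if t == 0:
            out.append(y)
            continue
        prev = out[-1]
        if y == prev or prev == 0:
            out.append(y)
            continue
        w = w_gr if y == 0 else w_gg
        denom = frame[prev]
        ratio = np.inf if denom == 0 else frame[y] / denom
        out.append(y if ratio >= w else prev)
    return np.array(out)


def as_smoothed(frames):
    return SmoothedSequence(frames=np.asarray(frames))


class TestSmooth:
    def test_identical_frames_are_unchanged(self):
        p = np.full((3, 7), 1 / 7)
        out = smooth(PosteriorSequence(frames=p))
        np.testing.assert_allclose(out.frames, p[:1])

    def test_mean_of_one_hot_frames(self):
        frames = np.zeros((3, 7))
        frames[0, 1] = frames[1, 2] = frames[2, 3] = 1.0
        out = smooth(PosteriorSequence(frames=frames)).frames[0]
        expected = np.array([0, 1, 1, 1, 0, 0, 0]) / 3
        np.testing.assert_allclose(out, expected)

    def test_normalization_conserved_exactly(self, rng):
        frames = random_simplex(rng, 99)
        out = smooth(PosteriorSequence(frames=frames))
        np.testing.assert_allclose(out.frames.sum(axis=1), 1.0, atol=1e-9)
        assert out.frames.shape[0] == 33
        assert out.step_ms == 150.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            smooth(PosteriorSequence(frames=np.full((2, 7), 1 / 7)))

    def test_truth_labels_align_with_triples(self):
        labels = np.array([0, 0, 2, 2, 2, 2, 0, 2, 2])
        np.testing.assert_array_equal(smooth_labels(labels), [0, 2, 2])
        # rest/grasp tie inside a triple breaks toward the grasp
        assert smooth_labels(np.array([0, 3, 0]))[0] == 0  # 2 rest > 1 grasp
        assert smooth_labels(np.array([0, 3, 3]))[0] == 3


class TestGate:
    def test_blocked_grasp_switch_holds(self):
        frames = np.zeros((2, 7))
        frames[0, 1] = 1.0
        frames[1, 2], frames[1, 1] = 0.60, 0.30  # ratio 2.0 < 2.5
        trace = gate(as_smoothed(frames))
        assert trace.output_states[1] == 1
        assert trace.rule_fired[1] == "hold"
        assert trace.ratios[1] == pytest.approx(2.0)

    def test_allowed_rest_switch_fires(self):
        frames = np.zeros((2, 7))
        frames[0, 1] = 1.0
        frames[1, 0], frames[1, 1] = 0.75, 0.25  # ratio 3.0 >= 2.5
        trace = gate(as_smoothed(frames))
        assert trace.output_states[1] == 0
        assert trace.rule_fired[1] == "switch"

    def test_zero_thresholds_reduce_to_argmax(self, rng):
        frames = random_simplex(rng, 200)
        cfg = TransitionConfig(w_grasp_to_grasp=0.0, w_grasp_to_rest=0.0)
        trace = gate(as_smoothed(frames), cfg)
        np.testing.assert_array_equal(trace.output_states, frames.argmax(axis=1))

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        for _ in range(1000):
            n = rng.integers(2, 30)
            frames = random_simplex(rng, n, concentration=rng.uniform(0.2, 3.0))
            w_gg, w_gr = rng.uniform(0.0, 4.0, size=2)
            cfg = TransitionConfig(w_grasp_to_grasp=w_gg, w_grasp_to_rest=w_gr)
            got = gate(as_smoothed(frames), cfg).output_states
            np.testing.assert_array_equal(got, brute_force_gate(frames, w_gg, w_gr))

    def test_infinite_thresholds_make_grasp_absorbing(self, rng):
        frames = random_simplex(rng, 300)
        cfg = TransitionConfig(w_grasp_to_grasp=np.inf, w_grasp_to_rest=np.inf)
        states = gate(as_smoothed(frames), cfg).output_states
        grasp_steps = np.flatnonzero(states != 0)
        if grasp_steps.size:
            first = grasp_steps[0]
            assert np.all(states[first:] == states[first])

    def test_switch_count_non_increasing_in_grasp_threshold(self, rng):
        frames = random_simplex(rng, 500)
        counts = []
        for w in [0.0, 1.0, 2.0, 3.0, 5.0]:
            states = gate(
                as_smoothed(frames), TransitionConfig(w_grasp_to_grasp=w, w_grasp_to_rest=1.0)
            ).output_states
            is_gg = (states[:-1] != 0) & (states[1:] != 0) & (states[:-1] != states[1:])
            counts.append(int(is_gg.sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gate(as_smoothed(np.zeros((0, 7))))


def make_dipped_sequence(rng, n=120, dip_every=10):
    """Grasp-c1 plateau whose posteriors dip toward rest with ratio < 2."""
    frames = np.tile(np.array([0.1, 0.8, 0.02, 0.02, 0.02, 0.02, 0.02]), (n, 1))
    for i in range(dip_every, n, dip_every):
        frames[i] = [0.55, 0.35, 0.02, 0.02, 0.02, 0.02, 0.02]  # ratio 1.57
    truth = np.ones(n, dtype=int)
    return frames, truth


class TestThresholdSearch:
    def test_grid_evaluates_81_pairs(self, rng):
        frames, truth = make_dipped_sequence(rng)
        _, table = optimize_thresholds([(as_smoothed(frames), truth)], DEFAULT_GRID)
        assert table.shape == (9, 9)
        assert len(DEFAULT_GRID) ** 2 == 81

    def test_perfect_labels_tie_break_to_smallest(self, rng):
        frames = np.zeros((20, 7))
        frames[:10, 1] = 1.0
        frames[10:, 0] = 1.0
        truth = frames.argmax(axis=1)
        best, table = optimize_thresholds([(as_smoothed(frames), truth)], DEFAULT_GRID)
        assert np.allclose(table, table[0, 0])
        assert (best.w_grasp_to_grasp, best.w_grasp_to_rest) == (1.0, 1.0)

    def test_rest_dips_drive_rest_threshold_up(self, rng):
        frames, truth = make_dipped_sequence(rng)
        best, _ = optimize_thresholds([(as_smoothed(frames), truth)], DEFAULT_GRID)
        assert best.w_grasp_to_rest > 1.0
        # and gating at the selected config removes the dips while w=1 does not
        gated = gate(as_smoothed(frames), best).output_states
        ungated = gate(
            as_smoothed(frames), TransitionConfig(w_grasp_to_grasp=1.0, w_grasp_to_rest=1.0)
        ).output_states
        assert (gated == truth).mean() > (ungated == truth).mean()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            optimize_thresholds([], DEFAULT_GRID)
        with pytest.raises(ValueError):
            optimize_thresholds([(as_smoothed(np.full((3, 7), 1 / 7)), np.zeros(3))], [])


class TestFalseNegativeRate:
    def test_perfect_trace_has_zero_rate(self):
        truth = np.array([0, 1, 1, 2, 0])
        rate, cm = false_negative_rate(truth, truth)
        assert rate == 0.0
        assert cm.shape == (7, 7)
        assert cm.sum() == truth.size

    def test_all_rest_against_all_grasp_is_one(self):
        rate, _ = false_negative_rate(np.zeros(10, dtype=int), np.full(10, 3))
        assert rate == 1.0

    def test_undefined_without_grasp_frames(self):
        rate, _ = false_negative_rate(np.zeros(5, dtype=int), np.zeros(5, dtype=int))
        assert np.isnan(rate)

    def test_gating_reduces_false_negatives_on_dipped_posteriors(self, rng):
        frames, truth = make_dipped_sequence(rng)
        sm = as_smoothed(frames)
        ungated = sm.frames.argmax(axis=1)
        gated = gate(sm).output_states
        fn_before, _ = false_negative_rate(ungated, truth)
        fn_after, _ = false_negative_rate(gated, truth)
        assert fn_after < fn_before
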