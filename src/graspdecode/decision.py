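"""Sequential decision layer on top of the posterior classifier.

Two stages:

1. *Posterior smoothing* - the arithmetic mean of every three adjacent
   posterior frames (a soft majority vote), emitted every 150 ms.
2. *State-transition gating* - a knowledge-based hysteresis rule: once a
   grasp is held, the decoder switches to another grasp (threshold
   ``w_grasp_to_grasp``) or back to rest (threshold ``w_grasp_to_rest``)
   only when the candidate's smoothed posterior exceeds the held class's
   by that ratio. Both ratios are read from the current smoothed frame.
   Leaving rest is ungated by default: commanding a grasp promptly is the
   cheap direction, while dropping an object (a false negative) is the
   costly one.

Both thresholds default to 2.5, the optimum of a 1..5 (step 0.5) grid
search; ``optimize_thresholds`` reproduces that search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gru import PosteriorSequence

__all__ = [
    "SmoothedSequence",
    "TransitionConfig",
    "DecisionTrace",
    "smooth",
    "smooth_labels",
    "gate",
    "optimize_thresholds",
    "false_negative_rate",
    "confusion_matrix",
]

logger = logging.getLogger(__name__)

N_CLASSES = 7
DEFAULT_GRID = tuple(np.arange(1.0, 5.0 + 1e-9, 0.5))


@dataclass
class SmoothedSequence:
    """Mean-of-three posterior frames at 150 ms cadence.

    ``source_triples[i]`` holds the three source-frame indices averaged
    into output frame ``i`` (non-overlapping consecutive triples).
    """

    frames: np.ndarray
    step_ms: float = 150.0
    source_triples: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=int))
    timestamps_ms: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class TransitionConfig:
    """Hysteresis thresholds of the state machine (>= 1 in normal use)."""

    w_grasp_to_grasp: float = 2.5
    w_grasp_to_rest: float = 2.5
    rest_exit_gated: bool = False

    def __post_init__(self) -> None:
        if self.w_grasp_to_grasp < 0 or self.w_grasp_to_rest < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class DecisionTrace:
    """Per-step record of the gated decoder."""

    raw_labels: np.ndarray     # argmax of each smoothed frame
    output_states: np.ndarray  # gated decisions in 0..6
    ratios: np.ndarray         # evaluated probability ratio (nan where ungated)
    rule_fired: np.ndarray     # 'hold' | 'switch' | 'pass-through' per step

    def __len__(self) -> int:
        return self.output_states.size


def smooth(posteriors: PosteriorSequence) -> SmoothedSequence:
    """Average non-overlapping triples of consecutive posterior frames.

    With a 50 ms input cadence the output cadence is 150 ms. Requires at
    least three frames; a trailing remainder of one or two frames is
    dropped. Normalization is preserved exactly (mean of simplex points).
    """
    frames = np.asarray(posteriors.frames, dtype=float)
    n = frames.shape[0]
    if n < 3:
        raise ValueError("smoothing requires at least three posterior frames")
    n_out = n // 3
    triples = np.arange(3 * n_out).reshape(n_out, 3)
    out = frames[: 3 * n_out].reshape(n_out, 3, -1).mean(axis=1)
    ts = np.asarray(posteriors.timestamps_ms)
    return SmoothedSequence(
        frames=out,
        step_ms=3 * posteriors.step_ms,
        source_triples=triples,
        timestamps_ms=ts[triples[:, 1]] if ts.size >= 3 * n_out else np.array([]),
    )


def smooth_labels(labels: np.ndarray, n_out: int | None = None) -> np.ndarray:
    """Majority truth label per non-overlapping frame triple (ties -> grasp,
    then lowest class index); aligns per-frame truth with `smooth` output."""
    labels = np.asarray(labels)
    if n_out is None:
        n_out = labels.size // 3
    trip = labels[: 3 * n_out].reshape(n_out, 3)
    out = np.empty(n_out, dtype=labels.dtype)
    for i, row in enumerate(trip):
        counts = np.bincount(row, minlength=N_CLASSES)
        grasp_best = counts[1:].argmax() + 1
        out[i] = 0 if counts[0] > counts[grasp_best] else grasp_best
    return out


def gate(smoothed: SmoothedSequence, config: TransitionConfig = TransitionConfig()) -> DecisionTrace:
    """Run the state-transition rules over a smoothed sequence.

    Per step: ``y = argmax`` of the current frame. From rest the decoder
    passes through (unless ``rest_exit_gated``). From a held grasp it
    switches to ``y`` only if ``p(y)/p(held) >= w`` for the transition type,
    else it holds. A zero denominator makes the ratio +inf (switch allowed).
    """
    frames = np.asarray(smoothed.frames, dtype=float)
    if frames.size == 0:
        raise ValueError("empty smoothed sequence")
    n = frames.shape[0]
    raw = frames.argmax(axis=1)
    out = np.empty(n, dtype=int)
    ratios = np.full(n, np.nan)
    rules = np.empty(n, dtype=object)
    out[0] = raw[0]
    rules[0] = "pass-through"
    for t in range(1, n):
        prev, y = out[t - 1], raw[t]
        if y == prev:
            out[t] = prev
            rules[t] = "pass-through"
            continue
        if prev == 0 and not config.rest_exit_gated:
            out[t] = y
            rules[t] = "pass-through"
            continue
        threshold = config.w_grasp_to_rest if y == 0 else config.w_grasp_to_grasp
        denom = frames[t, prev]
        if denom == 0.0:
            ratio = np.inf
            logger.info("zero held-state probability at step %d; allowing switch", t)
        else:
            ratio = frames[t, y] / denom
        ratios[t] = ratio
        if ratio >= threshold:
            out[t] = y
            rules[t] = "switch"
        else:
            out[t] = prev
            rules[t] = "hold"
    return DecisionTrace(
        raw_labels=raw, output_states=out, ratios=ratios, rule_fired=np.array(rules)
    )


def optimize_thresholds(
    sequences: Sequence[tuple[SmoothedSequence, np.ndarray]],
    grid: Sequence[float] = DEFAULT_GRID,
    objective: str = "accuracy",
    fn_weight: float = 2.0,
) -> tuple[TransitionConfig, np.ndarray]:
    """Exhaustive 2-D grid search over (w_grasp_to_grasp, w_grasp_to_rest).

    Scores gated frame accuracy against the aligned truth labels (objective
    ``'fn-weighted'`` counts a grasp-decoded-as-rest error ``fn_weight``
    times). Returns the best config (ties -> smaller thresholds, grasp-grasp
    first) and the full len(grid) x len(grid) score table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    if not sequences:
        raise ValueError("no sequences to optimize on")
    for seq, labels in sequences:
        if seq.frames.shape[0] != np.asarray(labels).size:
            raise ValueError("labels must align one-to-one with smoothed frames")
    scores = np.empty((len(grid), len(grid)))
    best, best_score = None, -np.inf
    for i, w_gg in enumerate(grid):
        for j, w_gr in enumerate(grid):
            cfg = TransitionConfig(w_grasp_to_grasp=w_gg, w_grasp_to_rest=w_gr)
            num = den = 0.0
            for seq, labels in sequences:
                states = gate(seq, cfg).output_states
                labels = np.asarray(labels)
                if objective == "accuracy":
                    num += float((states == labels).sum())
                    den += labels.size
                elif objective == "fn-weighted":
                    fn = (labels != 0) & (states == 0)
                    other = (states != labels) & ~fn
                    num += labels.size - (fn_weight * fn.sum() + other.sum())
                    den += labels.size
                else:
                    raise ValueError(f"unknown objective {objective!r}")
            score = num / den
            scores[i, j] = score
            if score > best_score:  # strict: ascending grid => smallest tie wins
                best, best_score = cfg, score
    return best, scores


def confusion_matrix(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """7 x 7 confusion matrix, rows = truth c0..c6, columns = prediction."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (truth, predicted), 1)
    return cm


def false_negative_rate(
    states: np.ndarray | DecisionTrace, truth: np.ndarray
) -> tuple[float, np.ndarray]:
    """Share of true grasp frames decoded as rest, plus the confusion matrix.

    Returns nan for the rate (and logs a warning) when the truth contains no
    grasp frames.
    """
    if isinstance(states, DecisionTrace):
        states = states.output_states
    states = np.asarray(states, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if states.size != truth.size:
        raise ValueError("states and truth must have equal length")
    cm = confusion_matrix(truth, states)
    grasp = truth != 0
    if not grasp.any():
        logger.warning("false-negative rate undefined: no grasp frames in truth")
        return float("nan"), cm
    rate = float(((states == 0) & grasp).sum() / grasp.sum())
    return rate, cm
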