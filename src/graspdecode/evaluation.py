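"""Experiment harness: incremental split, per-subject averaging, stage tables.

The protocol mimics real prosthesis calibration: for every subject and
session the first 20 repetitions train, the last 10 test, so training data
always precedes test data in time; a violation raises
``TemporalLeakageError``. Each subject's accuracy is averaged over repeats
(which vary only seeds), and the grand mean is the mean of the per-subject
means.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .decision import (
    DecisionTrace,
    TransitionConfig,
    false_negative_rate,
    gate,
    smooth,
    smooth_labels,
)
from .features import ClassifierSpec, build_feature_table, fit_classical
from .gru import GruConfig, GruPosteriorNet, PosteriorSequence
from .preprocess import FilterSpec, WindowSpec, filter_recording, segment, window_repetitions

__all__ = [
    "SplitSpec",
    "TemporalLeakageError",
    "check_temporal_split",
    "ExperimentReport",
    "run_protocol",
    "StageResult",
    "evaluate_stages",
    "compare_stages",
]


class TemporalLeakageError(RuntimeError):
    """A test window would precede the end of the training data in time."""


@dataclass(frozen=True)
class SplitSpec:
    """Incremental repetition split: training strictly precedes testing."""

    train_repetitions: tuple[int, ...] = tuple(range(1, 21))
    test_repetitions: tuple[int, ...] = tuple(range(21, 31))
    n_repeats: int = 10

    def __post_init__(self) -> None:
        train = set(self.train_repetitions)
        test = set(self.test_repetitions)
        if train & test:
            raise ValueError("a repetition cannot be in both splits")
        if max(self.train_repetitions) > min(self.test_repetitions):
            raise ValueError("training repetitions must precede test repetitions")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def check_temporal_split(train_ts: np.ndarray, test_ts: np.ndarray) -> None:
    """Raise TemporalLeakageError unless every test timestamp follows every
    training timestamp of the same session."""
    train_ts, test_ts = np.asarray(train_ts), np.asarray(test_ts)
    if train_ts.size == 0 or test_ts.size == 0:
        return
    if test_ts.min() <= train_ts.max():
        raise TemporalLeakageError(
            f"test window at {test_ts.min():.0f} ms does not follow the last "
            f"training window at {train_ts.max():.0f} ms"
        )


@dataclass
class ExperimentReport:
    """Protocol results with the aggregation identity enforced."""

    pipeline: str
    per_subject_accuracy: dict[int, float]
    grand_mean: float
    fn_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    confusion_matrices: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    config_snapshot: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        expected = float(np.mean(list(self.per_subject_accuracy.values())))
        if not np.isclose(self.grand_mean, expected, rtol=0, atol=1e-12):
            raise ValueError("grand mean must equal the mean of per-subject means")
        if not all(0.0 <= a <= 1.0 for a in self.per_subject_accuracy.values()):
            raise ValueError("accuracies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": s, "accuracy": a} for s, a in sorted(self.per_subject_accuracy.items())
        ]
        rows.append({"subject": "mean", "accuracy": self.grand_mean})
        return pd.DataFrame(rows)


def _derive_seed(master: int, *parts: int) -> int:
    return int(np.random.SeedSequence([master, *parts]).generate_state(1)[0] % (2**31))


def _split_masks(reps: np.ndarray, split: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.isin(reps, split.train_repetitions),
        np.isin(reps, split.test_repetitions),
    )


def run_protocol(
    study: Sequence,
    pipeline: Literal["classical", "gru+decision"] = "gru+decision",
    split: SplitSpec = SplitSpec(),
    seed: int = 0,
    classifier: ClassifierSpec = ClassifierSpec("linear-SVM"),
    classical_window: WindowSpec = WindowSpec(300.0, 150.0),
    gru_config: GruConfig | None = None,
    transition: TransitionConfig = TransitionConfig(),
    filter_spec: FilterSpec = FilterSpec(),
    filter_fmg: bool = False,
    train_window_stride: int = 2,
) -> ExperimentReport:
    """Run the full train/test protocol on a simulated study.

    ``classical`` trains the baseline classifier on fused EMG-FMG features
    (300 ms windows stepped 150 ms, matching the decision cadence of the
    deep pipeline). ``gru+decision`` trains the GRU on 100 ms / 50 ms raw
    filtered windows, then smooths and gates the posterior stream; its
    accuracy is scored on the gated 150 ms decisions. GRU training uses
    every ``train_window_stride``-th window (50 %-overlapping neighbours
    are near-duplicates; the default keeps every second).
    """
    min_reps = min(len(rec.cycle_starts) for rec in study)
    if min_reps < max(split.test_repetitions):
        raise ValueError(
            f"every session needs >= {max(split.test_repetitions)} repetitions, found {min_reps}"
        )
    subjects = sorted({rec.subject_id for rec in study})
    filtered = [filter_recording(rec, filter_spec, filter_fmg) for rec in study]

    per_subject: dict[int, float] = {}
    fn_rates: dict[int, dict[str, float]] = {}
    confusions: dict[int, dict[str, np.ndarray]] = {}
    for subj in subjects:
        sessions = [rec for rec in filtered if rec.subject_id == subj]
        if pipeline == "classical":
            acc = _classical_subject(sessions, split, classifier, classical_window, seed, subj)
            per_subject[subj] = acc
        elif pipeline == "gru+decision":
            acc, fn, cms = _gru_subject(
                sessions, split, gru_config, transition, seed, subj, train_window_stride
            )
            per_subject[subj] = acc
            fn_rates[subj] = fn
            confusions[subj] = cms
        else:
            raise ValueError(f"unknown pipeline {pipeline!r}")

    snapshot = {
        "pipeline": pipeline,
        "split": asdict(split),
        "seed": seed,
        "filter": asdict(filter_spec),
        "filter_fmg": filter_fmg,
    }
    if pipeline == "classical":
        snapshot["classifier"] = {"family": classifier.family, **classifier.hyperparams}
        snapshot["window"] = asdict(classical_window)
    else:
        snapshot["gru"] = asdict(gru_config) if gru_config else "default"
        snapshot["transition"] = asdict(transition)
        snapshot["train_window_stride"] = train_window_stride
    return ExperimentReport(
        pipeline=pipeline,
        per_subject_accuracy=per_subject,
        grand_mean=float(np.mean(list(per_subject.values()))),
        fn_rates=fn_rates,
        confusion_matrices=confusions,
        config_snapshot=snapshot,
        seed=seed,
    )


def _classical_subject(
    sessions, split: SplitSpec, spec: ClassifierSpec, window: WindowSpec, seed: int, subj: int
) -> float:
    train_X, train_y, test_X, test_y = [], [], [], []
    for rec in sessions:
        table = build_feature_table(rec, window, "EMG-FMG")
        tr, te = _split_masks(table.repetitions, split)
        check_temporal_split(table.timestamps_ms[tr], table.timestamps_ms[te])
        train_X.append(table.vectors[tr])
        train_y.append(table.labels[tr])
        test_X.append(table.vectors[te])
        test_y.append(table.labels[te])
    from .features import FeatureTable  # local import to avoid cycle at module load

    table0 = build_feature_table(sessions[0], window, "EMG-FMG")
    train = FeatureTable(
        vectors=np.vstack(train_X),
        feature_names=table0.feature_names,
        modality="EMG-FMG",
        labels=np.concatenate(train_y),
        window_spec=window,
        timestamps_ms=np.arange(sum(len(y) for y in train_y), dtype=float),
    )
    X_test = np.vstack(test_X)
    y_test = np.concatenate(test_y)
    accs = [
        float(np.mean(fit_classical(train, spec, seed=_derive_seed(seed, subj, rep)).predict(X_test) == y_test))
        for rep in range(split.n_repeats)
    ]
    return float(np.mean(accs))


def _gru_subject(
    sessions,
    split: SplitSpec,
    gru_config: GruConfig | None,
    transition: TransitionConfig,
    seed: int,
    subj: int,
    stride: int,
):
    window = WindowSpec(100.0, 50.0)
    segmented = []
    for rec in sessions:
        windows, ts, labels = segment(rec, window)
        reps = window_repetitions(ts, rec.cycle_starts, rec.sampling_rate)
        tr, te = _split_masks(reps, split)
        check_temporal_split(ts[tr], ts[te])
        segmented.append((windows, ts, labels, tr, te))
    train_w = np.concatenate([w[tr][::stride] for w, _, _, tr, _ in segmented])
    train_y = np.concatenate([lab[tr][::stride] for _, _, lab, tr, _ in segmented])

    base = gru_config or GruConfig()
    accs = []
    fn_first: dict[str, float] = {}
    cms_first: dict[str, np.ndarray] = {}
    for rep in range(split.n_repeats):
        from dataclasses import replace

        cfg = replace(base, seed=_derive_seed(seed, subj, rep))
        net = GruPosteriorNet(cfg)
        net.fit(train_w, train_y)
        correct = total = 0
        smoothed_states, gated_states, truths = [], [], []
        for windows, ts, labels, _, te in segmented:
            posts = PosteriorSequence(
                frames=net.predict_proba(windows[te]), step_ms=window.step_ms,
                timestamps_ms=ts[te],
            )
            sm = smooth(posts)
            truth = smooth_labels(labels[te], sm.frames.shape[0])
            trace = gate(sm, transition)
            smoothed_states.append(sm.frames.argmax(axis=1))
            gated_states.append(trace.output_states)
            truths.append(truth)
            correct += int((trace.output_states == truth).sum())
            total += truth.size
        accs.append(correct / total)
        if rep == 0:
            truth_all = np.concatenate(truths)
            fn_b, cm_b = false_negative_rate(np.concatenate(smoothed_states), truth_all)
            fn_a, cm_a = false_negative_rate(np.concatenate(gated_states), truth_all)
            fn_first = {"before_gating": fn_b, "after_gating": fn_a}
            cms_first = {"before_gating": cm_b, "after_gating": cm_a}
    return float(np.mean(accs)), fn_first, cms_first


# --------------------------------------------------------------------- stages
@dataclass(frozen=True)
class StageResult:
    """Metrics of one post-processing stage of the decoder output."""

    stage: str
    accuracy: float
    fn_rate: float
    switch_count: int
    seed: int = 0


def _switches(states: np.ndarray) -> int:
    return int((np.diff(np.asarray(states)) != 0).sum())


def evaluate_stages(
    posteriors: PosteriorSequence,
    window_truth: np.ndarray,
    transition: TransitionConfig = TransitionConfig(),
    seed: int = 0,
) -> tuple[StageResult, StageResult, StageResult]:
    """Raw argmax (50 ms), smoothed argmax (150 ms), gated output (150 ms)."""
    raw_states = posteriors.frames.argmax(axis=1)
    fn_raw, _ = false_negative_rate(raw_states, window_truth[: raw_states.size])
    raw = StageResult(
        "raw",
        float(np.mean(raw_states == window_truth[: raw_states.size])),
        fn_raw,
        _switches(raw_states),
        seed,
    )
    sm = smooth(posteriors)
    truth = smooth_labels(np.asarray(window_truth), sm.frames.shape[0])
    sm_states = sm.frames.argmax(axis=1)
    fn_sm, _ = false_negative_rate(sm_states, truth)
    smoothed = StageResult(
        "smoothed", float(np.mean(sm_states == truth)), fn_sm, _switches(sm_states), seed
    )
    trace = gate(sm, transition)
    fn_g, _ = false_negative_rate(trace, truth)
    gated = StageResult(
        "gated",
        float(np.mean(trace.output_states == truth)),
        fn_g,
        _switches(trace.output_states),
        seed,
    )
    return raw, smoothed, gated


def compare_stages(
    report_raw: StageResult, report_smoothed: StageResult, report_gated: StageResult
) -> pd.DataFrame:
    """Assemble the per-stage table; all stages must come from the same run."""
    stages = (report_raw, report_smoothed, report_gated)
    if len({s.seed for s in stages}) != 1:
        raise ValueError("stage results come from different runs (seeds differ)")
    return pd.DataFrame(
        [
            {
                "stage": s.stage,
                "accuracy": s.accuracy,
                "fn_rate": s.fn_rate,
                "switch_count": s.switch_count,
            }
            for s in stages
        ]
    )
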