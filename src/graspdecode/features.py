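"""Time-domain features and classical baseline classifiers.

Per window and channel: mean absolute value (MAV), root mean square (RMS),
waveform length (WL), and zero-crossing count (ZC). With five channels per
modality a window yields a 20-dimensional vector per modality, 40 fused.

Baselines: linear SVM, 2nd-order polynomial SVM, LDA, and kNN (k=50), each
behind a z-score normalizer fit on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .preprocess import FilterSpec, WindowSpec, filter_recording, segment, window_repetitions

__all__ = [
    "FEATURES",
    "FeatureTable",
    "ClassifierSpec",
    "extract_features",
    "feature_matrix",
    "build_feature_table",
    "fuse",
    "fit_classical",
    "modality_experiment",
]

FEATURES = ("MAV", "RMS", "WL", "ZC")

Modality = Literal["EMG", "FMG", "EMG-FMG"]


def extract_features(window: np.ndarray, zc_deadband: float = 0.0) -> np.ndarray:
    """Feature vector of one channels x samples window, channel-major:
    (ch1 MAV, ch1 RMS, ch1 WL, ch1 ZC, ch2 MAV, ...).

    ZC counts strict sign changes whose amplitude step exceeds the deadband
    (default 0: a pure sign change).
    """
    return feature_matrix(np.asarray(window)[None], zc_deadband)[0]


def feature_matrix(windows: np.ndarray, zc_deadband: float = 0.0) -> np.ndarray:
    """Vectorized features for a (n_windows, channels, samples) stack."""
    w = np.asarray(windows, dtype=float)
    if w.ndim != 3 or w.shape[-1] < 1:
        raise ValueError("expected a non-empty (n, channels, samples) array")
    if not np.isfinite(w).all():
        n, c, _ = np.unravel_index(np.argmin(np.isfinite(w)), w.shape)
        raise ValueError(f"non-finite sample in window {n}, channel {c}")
    mav = np.abs(w).mean(axis=-1)
    rms = np.sqrt((w**2).mean(axis=-1))
    dif = np.diff(w, axis=-1)
    wl = np.abs(dif).sum(axis=-1)
    crossing = (w[..., :-1] * w[..., 1:] < 0) & (np.abs(dif) >= zc_deadband)
    zc = crossing.sum(axis=-1).astype(float)
    return np.stack([mav, rms, wl, zc], axis=-1).reshape(w.shape[0], -1)


def _feature_names(modality: str, n_channels: int) -> list[str]:
    return [f"{modality}{ch + 1}_{f}" for ch in range(n_channels) for f in FEATURES]


@dataclass
class FeatureTable:
    """Per-window feature vectors with their timestamps and labels."""

    vectors: np.ndarray          # (n_windows, n_features)
    feature_names: list[str]
    modality: str
    labels: np.ndarray           # (n_windows,) in 0..6
    window_spec: WindowSpec
    timestamps_ms: np.ndarray
    repetitions: np.ndarray | None = None  # 1-based cycle index per window

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != self.labels.size:
            raise ValueError("rows and labels misaligned")
        if self.vectors.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def select(self, mask: np.ndarray) -> "FeatureTable":
        return replace(
            self,
            vectors=self.vectors[mask],
            labels=self.labels[mask],
            timestamps_ms=self.timestamps_ms[mask],
            repetitions=None if self.repetitions is None else self.repetitions[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=self.feature_names)
        df.insert(0, "timestamp_ms", self.timestamps_ms)
        df.insert(1, "label", self.labels)
        return df


def build_feature_table(
    recording,
    spec: WindowSpec = WindowSpec(),
    modality: Modality = "EMG-FMG",
    zc_deadband: float = 0.0,
) -> FeatureTable:
    """Segment a recording and extract features for one modality."""
    windows, timestamps, labels = segment(recording, spec)
    n_emg = recording.emg.shape[0]
    if modality == "EMG":
        windows = windows[:, :n_emg]
    elif modality == "FMG":
        windows = windows[:, n_emg:]
    elif modality != "EMG-FMG":
        raise ValueError(f"unknown modality {modality!r}")
    if modality == "EMG-FMG":
        names = _feature_names("EMG", n_emg) + _feature_names(
            "FMG", recording.fmg.shape[0]
        )
    else:
        names = _feature_names(modality, windows.shape[1])
    reps = window_repetitions(timestamps, recording.cycle_starts, recording.sampling_rate)
    return FeatureTable(
        vectors=feature_matrix(windows, zc_deadband),
        feature_names=names,
        modality=modality,
        labels=labels,
        window_spec=spec,
        timestamps_ms=timestamps,
        repetitions=reps,
    )


def fuse(emg_table: FeatureTable, fmg_table: FeatureTable) -> FeatureTable:
    """Row-wise concatenation of two aligned per-modality tables."""
    if len(emg_table) != len(fmg_table) or not np.array_equal(
        emg_table.timestamps_ms, fmg_table.timestamps_ms
    ):
        raise ValueError("tables are not aligned on window timestamps")
    if not np.array_equal(emg_table.labels, fmg_table.labels):
        raise ValueError("tables disagree on window labels")
    names = list(emg_table.feature_names) + list(fmg_table.feature_names)
    if len(set(names)) != len(names):  # e.g. fusing a table with itself
        names = [f"{t.modality}.{i}|{n}" for i, t in enumerate((emg_table, fmg_table)) for n in t.feature_names]
    return FeatureTable(
        vectors=np.hstack([emg_table.vectors, fmg_table.vectors]),
        feature_names=names,
        modality="EMG-FMG",
        labels=emg_table.labels.copy(),
        window_spec=emg_table.window_spec,
        timestamps_ms=emg_table.timestamps_ms.copy(),
        repetitions=emg_table.repetitions,
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the four baseline families with its fixed default settings."""

    family: Literal["linear-SVM", "poly2-SVM", "LDA", "kNN"] = "linear-SVM"
    hyperparams: dict = field(default_factory=dict)

    def make(self, seed: int = 0):
        hp = dict(self.hyperparams)
        if self.family == "linear-SVM":
            return LinearSVC(C=hp.pop("C", 1.0), dual=False, random_state=seed, **hp)
        if self.family == "poly2-SVM":
            # inhomogeneous kernel (1 + x.y)^2: a homogeneous quadratic is
            # sign-blind and cannot split standardized clusters
            return SVC(
                kernel="poly", degree=2, coef0=hp.pop("coef0", 1.0),
                C=hp.pop("C", 1.0), random_state=seed, **hp,
            )
        if self.family == "LDA":
            return LinearDiscriminantAnalysis(**hp)
        if self.family == "kNN":
            return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 50), **hp)
        raise ValueError(f"unknown classifier family {self.family!r}")


def fit_classical(train: FeatureTable, spec: ClassifierSpec, seed: int = 0) -> Pipeline:
    """Fit normalizer + classifier on training rows only."""
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("training set must contain at least two classes")
    if spec.family == "kNN":
        k = spec.hyperparams.get("n_neighbors", 50)
        if len(train) < k:
            raise ValueError(f"kNN requires at least k={k} training rows, got {len(train)}")
    model = Pipeline([("scale", StandardScaler()), ("clf", spec.make(seed))])
    model.fit(train.vectors, train.labels)
    return model


def modality_experiment(
    study: Sequence,
    steps_ms: Sequence[float] = (50.0, 100.0, 150.0, 200.0),
    specs: Sequence[ClassifierSpec] = (ClassifierSpec("linear-SVM"),),
    train_reps: range = range(1, 21),
    test_reps: range = range(21, 31),
    n_repeats: int = 10,
    seed: int = 0,
    modalities: Sequence[Modality] = ("EMG", "FMG", "EMG-FMG"),
    filter_spec: FilterSpec = FilterSpec(),
    filter_fmg: bool = False,
) -> pd.DataFrame:
    """Accuracy grid (classifier x modality x step size).

    For each step the window is twice the step (50% overlap). Per subject:
    train on repetitions 1-20, test on 21-30, repeated ``n_repeats`` times
    varying only the classifier seed, then averaged; the grid cell is the
    mean over subjects.

    EMG is band-pass filtered before feature extraction. FMG is kept
    unfiltered by default: its information is the slow force envelope,
    which the EMG band would suppress (pass ``filter_fmg=True`` for the
    strictly uniform treatment of both modalities).
    """
    steps_ms = list(steps_ms)
    subjects = sorted({rec.subject_id for rec in study})
    min_reps = min(len(rec.cycle_starts) for rec in study)
    if min_reps < max(test_reps):
        raise ValueError(
            f"protocol requires {max(test_reps)} repetitions per session, found {min_reps}"
        )
    study = [filter_recording(rec, filter_spec, filter_fmg) for rec in study]
    rows = []
    for step in steps_ms:
        wspec = WindowSpec(length_ms=2 * step, step_ms=step)
        # features are classifier- and modality-independent: extract the
        # fused table once, per-modality tables are column slices of it
        tables: dict[tuple[int, str], tuple[FeatureTable, FeatureTable]] = {}
        for subj in subjects:
            fused_sessions = [
                build_feature_table(rec, wspec, "EMG-FMG")
                for rec in study
                if rec.subject_id == subj
            ]
            for modality in modalities:
                per_session = [_modality_view(t, modality) for t in fused_sessions]
                train = _concat_split(per_session, train_reps)
                test = _concat_split(per_session, test_reps)
                tables[(subj, modality)] = (train, test)
        for spec in specs:
            for modality in modalities:
                per_subject = []
                for subj in subjects:
                    train, test = tables[(subj, modality)]
                    accs = [
                        float(
                            np.mean(
                                fit_classical(train, spec, seed=seed + rep).predict(
                                    test.vectors
                                )
                                == test.labels
                            )
                        )
                        for rep in range(n_repeats)
                    ]
                    per_subject.append(np.mean(accs))
                rows.append(
                    {
                        "classifier": spec.family,
                        "modality": modality,
                        "step_ms": step,
                        "accuracy": float(np.mean(per_subject)),
                    }
                )
    return pd.DataFrame(rows)


def _modality_view(fused: FeatureTable, modality: str) -> FeatureTable:
    if modality == "EMG-FMG":
        return fused
    cols = [i for i, n in enumerate(fused.feature_names) if n.startswith(modality)]
    if not cols:
        raise ValueError(f"no {modality} columns in fused table")
    return replace(
        fused,
        vectors=fused.vectors[:, cols],
        feature_names=[fused.feature_names[i] for i in cols],
        modality=modality,
    )


def _concat_split(tables: Sequence[FeatureTable], reps: range) -> FeatureTable:
    parts = [t.select(np.isin(t.repetitions, list(reps))) for t in tables]
    first = parts[0]
    return FeatureTable(
        vectors=np.vstack([p.vectors for p in parts]),
        feature_names=first.feature_names,
        modality=first.modality,
        labels=np.concatenate([p.labels for p in parts]),
        window_spec=first.window_spec,
        timestamps_ms=np.concatenate([p.timestamps_ms for p in parts]),
    )
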