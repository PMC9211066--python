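"""Signal conditioning for co-located EMG/FMG recordings.

Band-pass filtering, Teager-Kaiser energy, threshold onset detection on
FSR/TKE traces, ground-truth label extraction, and sliding-window
segmentation of multi-channel recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SignalRecording

__all__ = [
    "FilterSpec",
    "WindowSpec",
    "bandpass",
    "filter_recording",
    "tke",
    "detect_onset",
    "labels_from_fsr",
    "segment",
    "segment_array",
    "window_labels",
    "window_repetitions",
    "n_windows",
]

N_CLASSES = 7  # rest c0 + grasp classes c1..c6


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    The default 6th-order 20-450 Hz band removes motion artifact below the
    EMG band and noise above it. ``mode='zero-phase'`` applies
    forward-backward filtering (no group delay; offline use), ``'causal'``
    a single pass (streaming use).
    """

    order: int = 6
    band: tuple[float, float] = (20.0, 450.0)
    mode: Literal["zero-phase", "causal"] = "zero-phase"

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0.0 < low < high):
            raise ValueError(f"invalid band {self.band}: need 0 < low < high")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds.

    The analysis convention is a window twice the step (50% overlap);
    the decoder's operating point is 100 ms windows every 50 ms.
    """

    length_ms: float = 100.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.length_ms <= 0 or self.step_ms <= 0:
            raise ValueError("window length and step must be positive")
        if self.step_ms > self.length_ms:
            raise ValueError("step must not exceed window length")

    def in_samples(self, sampling_rate: float) -> tuple[int, int]:
        length = int(round(self.length_ms * sampling_rate / 1000.0))
        step = int(round(self.step_ms * sampling_rate / 1000.0))
        return length, step


def bandpass(
    x: np.ndarray, spec: FilterSpec = FilterSpec(), sampling_rate: float = 1000.0
) -> np.ndarray:
    """Band-pass filter one channel (or an array of channels on the last axis).

    Returns a same-length array. Zero-phase mode uses ``sosfiltfilt``;
    causal mode a single ``sosfilt`` pass.
    """
    low, high = spec.band
    nyq = sampling_rate / 2.0
    if high >= nyq:
        raise ValueError(
            f"band edge {high} Hz is not below the Nyquist frequency {nyq} Hz"
        )
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * spec.order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(spec.order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    if spec.mode == "zero-phase":
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def tke(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy, psi_i = x_i^2 - x_{i-1} * x_{i+1}.

    Output has the same length as the input; the two boundary samples copy
    their nearest interior value (psi[0] = psi[1], psi[-1] = psi[-2]).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("tke requires a 1-D series of length >= 3")
    psi = np.empty_like(x)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    psi[0] = psi[1]
    psi[-1] = psi[-2]
    return psi


def detect_onset(
    series: np.ndarray,
    sampling_rate: float = 1000.0,
    baseline_s: float = 1.0,
    k: float = 5.0,
    min_run_s: float = 0.05,
    merge_gap_s: float = 0.05,
) -> list[tuple[int, int]]:
    """Threshold-crossing onset detection.

    The threshold is ``mean + k * SD`` of the first ``baseline_s`` seconds
    (assumed rest). Returns maximal ``(onset, offset)`` index runs where the
    series exceeds the threshold, ``offset`` exclusive, after debouncing:
    gaps shorter than ``merge_gap_s`` are merged, then runs shorter than
    ``min_run_s`` are discarded.
    """
    series = np.asarray(series, dtype=float)
    n_base = int(round(baseline_s * sampling_rate))
    if series.size <= n_base:
        raise ValueError("series must be longer than the baseline window")
    base = series[:n_base]
    threshold = base.mean() + k * base.std()
    above = series > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(series.size)
    runs = list(zip(starts, ends))
    # merge gaps shorter than merge_gap_s
    max_gap = int(round(merge_gap_s * sampling_rate))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    min_run = int(round(min_run_s * sampling_rate))
    return [r for r in merged if r[1] - r[0] >= min_run]


def labels_from_fsr(
    fsr: np.ndarray,
    grasp_class: int,
    sampling_rate: float = 1000.0,
    baseline_s: float = 1.0,
    k: float = 5.0,
) -> np.ndarray:
    """Per-sample ground-truth labels from the object-contact FSR trace.

    Samples inside detected contact runs get ``grasp_class`` (1..6), all
    others rest (0).
    """
    if not 1 <= grasp_class <= 6:
        raise ValueError("grasp_class must be in 1..6")
    labels = np.zeros(np.asarray(fsr).size, dtype=np.int8)
    for on, off in detect_onset(fsr, sampling_rate, baseline_s, k):
        labels[on:off] = grasp_class
    return labels


def n_windows(n_samples: int, length: int, step: int) -> int:
    """Number of sliding windows: floor((n - length) / step) + 1."""
    if n_samples < length:
        return 0
    return (n_samples - length) // step + 1


def window_labels(labels: np.ndarray, length: int, step: int) -> np.ndarray:
    """Majority label per window; rest/grasp ties break toward the grasp.

    Uses cumulative class counts so the cost is O(n_classes * n_windows).
    """
    labels = np.asarray(labels)
    n_win = n_windows(labels.size, length, step)
    starts = np.arange(n_win) * step
    counts = np.empty((N_CLASSES, n_win), dtype=np.int64)
    for c in range(N_CLASSES):
        cs = np.concatenate(([0], np.cumsum(labels == c)))
        counts[c] = cs[starts + length] - cs[starts]
    grasp_best = counts[1:].argmax(axis=0) + 1  # ties -> lowest class index
    grasp_count = counts[1:].max(axis=0)
    return np.where(counts[0] > grasp_count, 0, grasp_best).astype(np.int8)


def segment_array(
    data: np.ndarray,
    labels: np.ndarray,
    spec: WindowSpec,
    sampling_rate: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment a channels x samples array into overlapping windows.

    Returns ``(windows, timestamps_ms, window_labels)`` where windows has
    shape (n_windows, channels, length) and each timestamp is the window
    start time. Windows start at multiples of the step.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = np.asarray(labels)
    if data.shape[1] != labels.size:
        raise ValueError("data and labels must have the same number of samples")
    length, step = spec.in_samples(sampling_rate)
    if data.shape[1] < length:
        raise ValueError("recording shorter than one window")
    n_win = n_windows(data.shape[1], length, step)
    views = sliding_window_view(data, length, axis=1)[:, ::step, :]  # (C, n, L)
    windows = np.ascontiguousarray(views[:, :n_win].transpose(1, 0, 2))
    timestamps = np.arange(n_win) * step * 1000.0 / sampling_rate
    return windows, timestamps, window_labels(labels, length, step)


def filter_recording(
    recording: "SignalRecording",
    spec: FilterSpec = FilterSpec(),
    filter_fmg: bool = True,
) -> "SignalRecording":
    """Band-pass filter a recording's signal channels; labels/FSR untouched.

    By default the FMG channels pass through the same 20-450 Hz filter as
    the EMG (the acquisition convention this pipeline follows); set
    ``filter_fmg=False`` to keep the FMG's low-frequency content instead.
    """
    from dataclasses import replace as _replace

    fmg = (
        bandpass(recording.fmg, spec, recording.sampling_rate)
        if filter_fmg
        else recording.fmg
    )
    return _replace(
        recording,
        emg=bandpass(recording.emg, spec, recording.sampling_rate),
        fmg=fmg,
    )


def segment(
    recording: "SignalRecording", spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment a recording into (n, 10, L) windows, EMG channels stacked
    above FMG channels, with window start timestamps (ms) and majority labels."""
    data = np.vstack([recording.emg, recording.fmg])
    return segment_array(data, recording.labels, spec, recording.sampling_rate)


def window_repetitions(
    timestamps_ms: np.ndarray, cycle_starts: np.ndarray, sampling_rate: float = 1000.0
) -> np.ndarray:
    """Map window start times to 1-based repetition (cycle) indices.

    Windows before the first cycle boundary belong to repetition 1.
    """
    starts_ms = np.asarray(cycle_starts) * 1000.0 / sampling_rate
    reps = np.searchsorted(starts_ms, np.asarray(timestamps_ms), side="right")
    return np.maximum(reps, 1).astype(int)
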