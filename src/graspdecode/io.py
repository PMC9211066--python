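"""HDF5 and CSV persistence for recordings, features, posteriors and traces."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decision import DecisionTrace
from .features import FeatureTable
from .gru import PosteriorSequence
from .preprocess import WindowSpec
from .simulate import SignalRecording

__all__ = [
    "save_recording",
    "load_recording",
    "recording_to_csv",
    "save_feature_table",
    "load_feature_table",
    "posteriors_to_csv",
    "trace_to_csv",
]


def save_recording(rec: SignalRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=rec.emg)
        f.create_dataset("fmg", data=rec.fmg)
        f.create_dataset("fsr", data=rec.fsr)
        f.create_dataset("labels", data=rec.labels)
        f.create_dataset("phase", data=rec.phase_track)
        f.create_dataset("cycle_starts", data=rec.cycle_starts)
        f.create_dataset("contact_intervals", data=rec.contact_intervals)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["class"] = rec.grasp_class
        f.attrs["subject"] = rec.subject_id
        f.attrs["seed"] = rec.seed


def load_recording(path: str | Path) -> SignalRecording:
    with h5py.File(path, "r") as f:
        return SignalRecording(
            emg=f["emg"][()],
            fmg=f["fmg"][()],
            fsr=f["fsr"][()],
            labels=f["labels"][()],
            phase_track=f["phase"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            grasp_class=int(f.attrs["class"]),
            subject_id=int(f.attrs["subject"]),
            seed=int(f.attrs["seed"]),
            cycle_starts=f["cycle_starts"][()],
            contact_intervals=f["contact_intervals"][()],
        )


def recording_to_csv(rec: SignalRecording, path: str | Path) -> None:
    """Inspection export: one column per channel plus the label track."""
    cols = {f"emg{c + 1}": rec.emg[c] for c in range(rec.emg.shape[0])}
    cols |= {f"fmg{c + 1}": rec.fmg[c] for c in range(rec.fmg.shape[0])}
    cols["fsr"] = rec.fsr
    cols["label"] = rec.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def save_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.to_frame()
    if table.repetitions is not None:
        df.insert(2, "repetition", table.repetitions)
    df.attrs["modality"] = table.modality
    df.to_csv(path, index=False)


def load_feature_table(
    path: str | Path, modality: str, window_spec: WindowSpec
) -> FeatureTable:
    df = pd.read_csv(path)
    reps = df.pop("repetition").to_numpy() if "repetition" in df else None
    ts = df.pop("timestamp_ms").to_numpy()
    labels = df.pop("label").to_numpy().astype(np.int8)
    return FeatureTable(
        vectors=df.to_numpy(float),
        feature_names=list(df.columns),
        modality=modality,
        labels=labels,
        window_spec=window_spec,
        timestamps_ms=ts,
        repetitions=reps,
    )


def posteriors_to_csv(posts: PosteriorSequence, path: str | Path) -> None:
    df = pd.DataFrame(posts.frames, columns=[f"p_c{i}" for i in range(7)])
    df.insert(0, "timestamp_ms", posts.timestamps_ms)
    df.to_csv(path, index=False)


def trace_to_csv(trace: DecisionTrace, path: str | Path, truth=None) -> None:
    df = pd.DataFrame(
        {
            "raw": trace.raw_labels,
            "output": trace.output_states,
            "ratio": trace.ratios,
            "rule": trace.rule_fired,
        }
    )
    if truth is not None:
        df.insert(0, "truth", np.asarray(truth))
    df.to_csv(path, index=False)
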