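"""Synthetic generator for reach-grasp-move-release-retract (RGMRR) sessions.

Emulates the statistical structure of co-located surface-EMG and
force-myography (FMG) recordings during pick-and-place cycles with dynamic
arm movement, plus the object-mounted FSR contact channel used as ground
truth:

* EMG is band-limited (20-450 Hz) Gaussian noise, amplitude-modulated by a
  grasp envelope (class-specific channel gains) plus an arm-movement
  envelope that is active while the arm travels - so muscle activity starts
  before object contact.
* FMG follows the grasp-force envelope through a mechanical delay and a
  low-pass stage, with a slow arm-position baseline drift - so its onset
  lags object contact.
* The FSR is a smoothed contact step; per-sample labels derive from it by
  thresholding, exactly as with real recordings.

Everything is driven by an explicit seed; identical inputs give identical
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preprocess import FilterSpec, bandpass, detect_onset, labels_from_fsr, tke

__all__ = [
    "PHASES",
    "RgmrrProtocol",
    "SubjectModel",
    "SignalRecording",
    "simulate_session",
    "simulate_study",
    "draw_subject",
    "onset_triplets",
]

PHASES = ("AR", "GP", "GO", "MO", "RO")
PHASE_INDEX = {name: i for i, name in enumerate(PHASES)}

DEFAULT_PHASE_MEANS = {"AR": 0.9, "GP": 0.6, "GO": 0.9, "MO": 1.0, "RO": 0.6}

# envelope geometry (seconds)
CONTACT_DELAY = 0.10   # fingers close this long after the GO phase starts
RELEASE_DELAY = 0.10   # object leaves the hand this long into RO
FSR_RAMP = 0.08
EMG_RAMP = 0.15
FORCE_RAMP = 0.15
RETRACT_S = 0.4        # arm-retraction movement at the start of each AR
FMG_LP_HZ = 5.0
FSR_NOISE_SD = 0.01
FMG_NOISE_SD = 0.01
FMG_REST_LEVEL = 0.02
POSITION_MOD_DEPTH = 0.5


@dataclass(frozen=True)
class RgmrrProtocol:
    """Task protocol: cycle structure AR->GP->GO->MO->RO, repeated."""

    n_cycles: int = 30
    phase_means: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_MEANS))
    phase_jitter_sd: float = 0.08
    grasp_class: int = 1
    sampling_rate: float = 1000.0
    n_emg_channels: int = 5
    n_fmg_channels: int = 5
    lead_in_s: float = 1.2  # quiet rest before cycle 1, used as the baseline second

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 1 <= self.grasp_class <= 6:
            raise ValueError("grasp_class must be in 1..6")
        if self.n_emg_channels < 1 or self.n_fmg_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if any(v <= 0 for v in self.phase_means.values()):
            raise ValueError("phase durations must be positive")
        if set(self.phase_means) != set(PHASES):
            raise ValueError(f"phase_means must define exactly {PHASES}")
        if self.sampling_rate != 1000.0:
            raise ValueError("the acquisition model is fixed at 1000 Hz")


@dataclass(frozen=True)
class SubjectModel:
    """Per-subject signal model.

    synergy_matrix maps grasp class -> per-channel activation gain and is
    shared by EMG and FMG (the force sensor sits over the same muscle);
    movement_gain scales the class-independent arm-movement EMG; emg_snr is
    the ratio (dB) of a unit grasp envelope to the resting EMG noise floor.
    """

    synergy_matrix: np.ndarray  # (n_channels, 6), gains in [0, 1]
    movement_gain: np.ndarray  # (n_channels,)
    fmg_lag: float = 0.15
    fmg_baseline_drift: float = 0.03
    emg_snr: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "synergy_matrix", np.asarray(self.synergy_matrix, dtype=float))
        object.__setattr__(self, "movement_gain", np.asarray(self.movement_gain, dtype=float))
        if (self.synergy_matrix < 0).any():
            raise ValueError("synergy_matrix must be non-negative")
        if self.fmg_lag < 0:
            raise ValueError("fmg_lag must be >= 0")
        cols = self.synergy_matrix
        for i in range(cols.shape[1]):
            for j in range(i + 1, cols.shape[1]):
                if np.allclose(cols[:, i], cols[:, j]):
                    raise ValueError("distinct classes must have non-identical synergy columns")


@dataclass
class SignalRecording:
    """One synchronized RGMRR session at 1 kHz."""

    emg: np.ndarray          # (n_emg_channels, n) zero-mean, mV scale
    fmg: np.ndarray          # (n_fmg_channels, n) non-negative, force-proportional
    fsr: np.ndarray          # (n,) object-contact force
    labels: np.ndarray       # (n,) int8 in 0..6, from FSR thresholding
    phase_track: np.ndarray  # (n,) int8 index into PHASES
    sampling_rate: float
    grasp_class: int
    subject_id: int = 0
    seed: int = 0
    cycle_starts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    contact_intervals: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=int))

    @property
    def n_samples(self) -> int:
        return self.fsr.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def phase_names(self) -> np.ndarray:
        return np.array(PHASES)[self.phase_track]


def _ramp_step(n: int, start: int, stop: int, ramp: int) -> np.ndarray:
    """Trapezoid on [start, stop) with half-cosine ramps of ``ramp`` samples."""
    env = np.zeros(n)
    start, stop = max(start, 0), min(stop, n)
    if stop <= start:
        return env
    ramp = min(ramp, max((stop - start) // 2, 1))
    t = np.arange(ramp)
    up = 0.5 * (1 - np.cos(np.pi * (t + 1) / ramp))
    env[start:stop] = 1.0
    env[start : start + ramp] = up
    env[stop - ramp : stop] = up[::-1]
    return env


def _bandlimited_noise(rng: np.random.Generator, n_channels: int, n: int) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to 20-450 Hz."""
    white = rng.standard_normal((n_channels, n))
    shaped = bandpass(white, FilterSpec(), 1000.0)
    return shaped / shaped.std(axis=1, keepdims=True)


def simulate_session(protocol: RgmrrProtocol, subject: SubjectModel) -> SignalRecording:
    """Generate one RGMRR session for one subject and one grasp class."""
    fs = protocol.sampling_rate
    rng = np.random.default_rng(subject.rng_seed)
    if subject.synergy_matrix.shape != (protocol.n_emg_channels, 6):
        raise ValueError("synergy_matrix shape must be (n_emg_channels, 6)")

    # --- timeline -----------------------------------------------------------
    jitter = protocol.phase_jitter_sd
    cycle_starts, bounds = [], []  # bounds: (phase_idx, start, stop) per phase
    t = int(round(protocol.lead_in_s * fs))
    lead_in = t
    for _ in range(protocol.n_cycles):
        cycle_starts.append(t)
        for name in PHASES:
            mean = protocol.phase_means[name]
            dur = max(rng.normal(mean, jitter), mean / 4)
            stop = t + int(round(dur * fs))
            bounds.append((PHASE_INDEX[name], t, stop))
            t = stop
    n = t + int(round(0.5 * fs))  # settle-out tail

    phase_track = np.zeros(n, dtype=np.int8)  # AR by default
    for idx, start, stop in bounds:
        phase_track[start:stop] = idx

    # --- envelopes ----------------------------------------------------------
    contact = np.zeros((protocol.n_cycles, 2), dtype=int)
    fsr_env = np.zeros(n)
    emg_grasp = np.zeros(n)
    force_env = np.zeros(n)
    move_env = np.zeros(n)
    elevation = np.zeros(n)
    carry = np.zeros(n)  # arm loaded with the object (MO and release)
    per_cycle = [bounds[i * 5 : (i + 1) * 5] for i in range(protocol.n_cycles)]
    for c, phases in enumerate(per_cycle):
        (_, ar0, ar1), (_, gp0, gp1), (_, go0, go1), (_, mo0, mo1), (_, ro0, ro1) = phases
        on = go0 + int(CONTACT_DELAY * fs)
        off = ro0 + int(RELEASE_DELAY * fs)
        contact[c] = (on, off)
        fsr_env += _ramp_step(n, on, off, int(FSR_RAMP * fs))
        force_env += _ramp_step(n, on, off, int(FORCE_RAMP * fs))
        # muscle activation spans the whole hold, beginning as the hand shapes
        emg_grasp += _ramp_step(n, go0, off, int(EMG_RAMP * fs))
        # arm travel: reach (GP), carry (MO), retract (start of next AR)
        move_env += _ramp_step(n, gp0, gp1, int(EMG_RAMP * fs))
        move_env += _ramp_step(n, mo0, mo1, int(EMG_RAMP * fs))
        move_env += _ramp_step(n, ro1, ro1 + int(RETRACT_S * fs), int(EMG_RAMP * fs))
        # arm elevation: raised over GP, lowered again as the object is released
        elevation += _ramp_step(n, gp0, ro1, int((gp1 - gp0)))
        carry += _ramp_step(n, mo0, ro1, int(0.3 * fs))
    np.clip(move_env, 0.0, 1.0, out=move_env)
    np.clip(elevation, 0.0, 1.0, out=elevation)
    np.clip(carry, 0.0, 1.0, out=carry)
    # FMG baseline drift follows the wrap-pressure change of the loaded arm:
    # small while the unloaded arm travels (GP/AR), full while carrying (MO)
    load = np.clip(0.3 * elevation + 0.7 * carry, 0.0, 1.0)

    mean_cycle = sum(protocol.phase_means.values())
    tgrid = np.arange(n) / fs

    # --- FSR ----------------------------------------------------------------
    fsr = fsr_env + FSR_NOISE_SD * rng.standard_normal(n)

    # --- EMG ----------------------------------------------------------------
    gains = subject.synergy_matrix[:, protocol.grasp_class - 1]  # (C,)
    noise_floor = 10.0 ** (-subject.emg_snr / 20.0)
    carrier = _bandlimited_noise(rng, protocol.n_emg_channels, n)
    floor = _bandlimited_noise(rng, protocol.n_emg_channels, n)
    phase_off = rng.uniform(0, 2 * np.pi, protocol.n_emg_channels)
    emg = np.empty((protocol.n_emg_channels, n))
    for ch in range(protocol.n_emg_channels):
        slow = np.sin(2 * np.pi * tgrid / mean_cycle + phase_off[ch])
        pos_mod = 1.0 + POSITION_MOD_DEPTH * slow * elevation
        amp = gains[ch] * emg_grasp * pos_mod + subject.movement_gain[ch] * move_env
        emg[ch] = carrier[ch] * amp + floor[ch] * noise_floor

    # --- FMG ----------------------------------------------------------------
    lag = int(round(subject.fmg_lag * fs))
    delayed = np.concatenate([np.zeros(lag), force_env])[:n]
    # single-pole low-pass: mechanical smoothing of the force sensor
    a = np.exp(-2 * np.pi * FMG_LP_HZ / fs)
    smooth_force = signal.lfilter([1 - a], [1, -a], delayed)
    fmg = np.empty((protocol.n_fmg_channels, n))
    for ch in range(protocol.n_fmg_channels):
        slow = np.sin(2 * np.pi * tgrid / mean_cycle + phase_off[ch % protocol.n_emg_channels])
        drift = subject.fmg_baseline_drift * load * (0.5 + 0.5 * slow)
        fmg[ch] = (
            FMG_REST_LEVEL
            + gains[ch % protocol.n_emg_channels] * smooth_force
            + drift
            + FMG_NOISE_SD * rng.standard_normal(n)
        )
    np.clip(fmg, 0.0, None, out=fmg)

    labels = labels_from_fsr(fsr, protocol.grasp_class, fs)
    return SignalRecording(
        emg=emg,
        fmg=fmg,
        fsr=fsr,
        labels=labels,
        phase_track=phase_track,
        sampling_rate=fs,
        grasp_class=protocol.grasp_class,
        seed=subject.rng_seed,
        cycle_starts=np.asarray(cycle_starts),
        contact_intervals=contact,
    )


def draw_subject(rng: np.random.Generator, n_channels: int = 5, seed: int = 0) -> SubjectModel:
    """Draw one subject's parameters from the documented population model.

    Grasp types engage largely the same forearm muscles, so synergy columns
    share a common activation base with a class-specific deviation - classes
    are separable but not trivially so. Movement gains are commensurate with
    grasp gains: during reach/carry the EMG looks like a grasp, which is
    exactly the interference the fusion strategy is meant to absorb.
    """
    base = rng.uniform(0.3, 0.9, size=(n_channels, 1))
    unique = rng.uniform(0.0, 1.0, size=(n_channels, 6))
    synergy = np.clip(0.65 * base + 0.35 * unique, 0.05, 1.0)
    return SubjectModel(
        synergy_matrix=synergy,
        movement_gain=rng.uniform(0.45, 0.8, size=n_channels),
        fmg_lag=rng.uniform(0.12, 0.18),
        fmg_baseline_drift=rng.uniform(0.02, 0.04),
        emg_snr=rng.uniform(13.0, 17.0),
        rng_seed=seed,
    )


def simulate_study(
    n_subjects: int,
    classes: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
    base_seed: int = 0,
    protocol: RgmrrProtocol = RgmrrProtocol(),
) -> list[SignalRecording]:
    """One session per subject x class, with deterministic seed fan-out."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    classes = tuple(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    if any(not 1 <= c <= 6 for c in classes):
        raise ValueError("classes must be in 1..6")
    root = np.random.SeedSequence(base_seed)
    recordings: list[SignalRecording] = []
    for subj, subj_ss in enumerate(root.spawn(n_subjects), start=1):
        param_ss, *session_ss = subj_ss.spawn(len(classes) + 1)
        # one subject keeps one body: parameters drawn once, only the
        # session noise seed varies across that subject's sessions
        subject = draw_subject(np.random.default_rng(param_ss), protocol.n_emg_channels)
        for cls, sess in zip(classes, session_ss):
            seed = int(sess.generate_state(1)[0] % (2**31))
            rec = simulate_session(
                replace(protocol, grasp_class=cls), replace(subject, rng_seed=seed)
            )
            rec.subject_id = subj
            recordings.append(rec)
    return recordings


def onset_triplets(
    rec: SignalRecording, tke_smooth_s: float = 0.02
) -> list[tuple[float, float, float]]:
    """Per-cycle (EMG, FSR, FMG) onset samples, or nan where not detected.

    EMG onset: threshold crossing of the moving-average-smoothed TKE of the
    channel with the largest synergy for the session class; FSR/FMG onsets:
    threshold crossings of the raw traces. All thresholds are
    mean + 5 SD of the first second, the convention used for ground truth.
    """
    fs = rec.sampling_rate
    ch = int(np.argmax(rec.emg.std(axis=1)))  # most active channel
    energy = tke(rec.emg[ch])
    w = max(int(tke_smooth_s * fs), 1)
    energy = np.convolve(energy, np.ones(w) / w, mode="same")
    emg_runs = detect_onset(energy, fs)
    fsr_runs = detect_onset(rec.fsr, fs)
    fmg_runs = detect_onset(rec.fmg[ch], fs)

    def first_in(runs: list[tuple[int, int]], start: int, stop: int) -> float:
        for on, off in runs:
            if start <= on < stop:
                return float(on)
        return float("nan")

    out = []
    starts = list(rec.cycle_starts) + [rec.n_samples]
    for c in range(len(rec.cycle_starts)):
        lo, hi = starts[c], starts[c + 1]
        out.append(
            (first_in(emg_runs, lo, hi), first_in(fsr_runs, lo, hi), first_in(fmg_runs, lo, hi))
        )
    return out
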