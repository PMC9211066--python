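# Methods

This note documents the models behind `graspdecode`: what the synthetic
signal generator emulates and deliberately does not, how each processing
stage is defined, the defaults that matter, and the design choices made
where more than one reading was defensible.

## Problem setting

A forearm band carries five co-located sensor modules, each measuring
surface EMG (electrical muscle activity, broadband 20–450 Hz, noise-like
and amplitude-modulated) and FMG (force myography: muscle bulge/stiffness
pressed against a force sensor, slow and force-proportional). A thin-film
FSR on the grasped object marks true contact. All channels are sampled at
1 kHz. The subject repeats a reach–grasp–move–release–retract (RGMRR)
cycle 30 times per grasp type; the decoder must emit one of seven states
(rest `c0`, grasps `c1..c6`) continuously while the arm moves.

Two facts make this hard and drive the whole design:

* **EMG leads contact.** Muscles fire during reach and carry, so EMG-only
  decoders confuse arm transport with grasping.
* **FMG lags contact.** The mechanical response builds up behind the grasp
  (low-pass behaviour) and its baseline shifts with arm posture.

## Synthetic data generator

Real recordings of this protocol are not publicly distributable, so the
generator produces sessions with the statistical structure above; every
downstream stage is tested against it.

Per cycle the phase sequence is AR→GP→GO→MO→RO (arm relax, grasp
preparation/reach, grasp object, move object, release object). Default
phase-duration means are AR 0.9 s, GP 0.6 s, GO 0.9 s, MO 1.0 s, RO 0.6 s
with 0.08 s jitter SD — a brisk but realistic pick-and-place pace giving
≈4 s cycles and ≈2-minute sessions. Each session starts with a 1.2 s quiet
lead-in so that "the first second" is a valid rest baseline for the
threshold conventions below.

Envelopes are trapezoids with half-cosine ramps (smooth, band-limited, no
filter ringing). Object contact runs from 0.1 s after GO starts to 0.1 s
into RO; the FSR is that step (80 ms ramps) plus N(0, 0.01) noise.

**EMG.** Each channel is unit-RMS Gaussian noise band-limited to
20–450 Hz (so simulated EMG survives the preprocessing filter), amplitude
modulated by

`a_ch(t) = synergy[ch, class] · grasp_env(t) · (1 + 0.5 · slow(t) · elevation(t)) + movement_gain[ch] · move_env(t)`

plus an additive band-limited noise floor at −SNR dB (default 15 dB,
subject-specific 13–17 dB). The grasp envelope starts when the hand shapes
around the object (100 ms before contact) and ends at release; the
movement envelope covers reach (GP), carry (MO), and a 0.4 s retraction at
the start of each AR. `slow(t)` is a sinusoid with period ≈ one cycle:
the arm-position modulation of the EMG during elevated-arm phases.

**Synergies.** Grasp types engage largely the same forearm muscles, so a
subject's 5×6 synergy matrix is `0.65 · base + 0.35 · unique` with
`base ~ U(0.3, 0.9)` per channel and `unique ~ U(0, 1)`: classes are
separable but share structure. Movement gains `U(0.45, 0.8)` are
commensurate with grasp gains — during transport the EMG genuinely looks
like a grasp, which is the interference the fusion strategy must absorb.

**FMG.** The contact-force envelope, scaled by the same synergy column,
delayed by `fmg_lag` (default 150 ms; subject-specific 120–180 ms) and
passed through a first-order 5 Hz low-pass (the sensor's mechanical
smoothing), on a 0.02 rest level, plus N(0, 0.01) noise and a
baseline drift `drift_amp · load(t) · (0.5 + 0.5 · slow(t))` where `load`
is small while the unloaded arm travels and full while carrying the object
(drift_amp default 0.03, subjects 0.02–0.04). Values are clipped
non-negative (a force sensor cannot pull).

**Labels** are derived exactly as with real recordings: threshold the FSR
at mean + 5·SD of the first second and assign the session's class inside
the detected runs, rest elsewhere. A few milliseconds around each ramp may
graze the threshold (noise + debouncing); everything else is crisp.

With these defaults the generator reproduces the target phenomenology: on
≥95 % of cycles (100 % in practice) the TKE-detected EMG onset precedes
the FSR onset, which precedes the FMG onset.

**What the generator does not emulate:** motor-unit physiology,
electrode shift, skin-impedance changes, fatigue, amputee-specific signal
alteration, crosstalk between sensor modules, or free-form arm
trajectories. Passing tests therefore demonstrate that the *algorithmic
chain* behaves as designed under the stated interference structure — not
clinical performance on real limbs.

Determinism: a study fans a base seed out through `SeedSequence`
(subject parameters once per subject, one child seed per session), so any
session is bit-reproducible in isolation.

## Preprocessing

* Band-pass: 6th-order Butterworth, 20–450 Hz, applied as second-order
  sections; zero-phase (forward–backward) for offline work, single-pass
  causal for streaming. EMG is always filtered. For FMG the filter is
  optional and **off by default in the experiment harness**: the FMG's
  information is its slow force envelope, which the EMG band would remove.
  `filter_recording(..., filter_fmg=True)` provides the strictly uniform
  treatment for comparison.
* Teager–Kaiser energy `ψ_i = x_i² − x_{i−1}·x_{i+1}`, full-length output
  with boundary samples copied from their neighbours.
* Onset detection: threshold = mean + k·SD of the first `baseline_s`
  seconds (defaults 1 s, k = 5), maximal above-threshold runs, gaps
  < 50 ms merged, runs < 50 ms discarded. The onset-ordering analysis
  smooths the TKE with a 20 ms moving average first; raw per-sample TKE of
  a stochastic signal flickers across any threshold.
* Segmentation: windows start at multiples of the step;
  `n = floor((N − L)/S) + 1`. Window label = majority of sample labels,
  ties broken toward the grasp (the decoder should err toward grasp
  sensitivity, because grasp-missed-as-rest is the costly error). The
  decoder's operating point is 100 ms windows every 50 ms → 10×100 inputs.

## Classical baselines

MAV, RMS, waveform length, and zero crossings per channel and window
(ZC deadband default 0 = pure sign change), channel-major. Feature
normalization is fit on training rows only and travels with the model.
Fixed classifier defaults: linear SVM = `LinearSVC` (liblinear, C = 1,
primal); poly-2 SVM = `SVC(kernel="poly", degree=2, coef0=1, C=1)` — the
inhomogeneous kernel, since a homogeneous quadratic is sign-blind and
cannot separate standardized clusters; LDA; kNN with k = 50 (an error if
fewer than 50 training rows). The modality experiment uses window = 2 ×
step at steps 50/100/150/200 ms, also for any larger step a caller passes.

## GRU posterior classifier

Architecture: per-channel z-score (statistics from the training windows;
the amplitude *level* is the signal, so normalization must be global, not
per window) → single GRU layer → dropout → ReLU → fully connected →
softmax over 7 classes. Gate convention is pinned because the parameter
count depends on it: dual-bias gates in order (r, z, n), giving
`3·(H·(I+H) + 2H)` GRU parameters — 72,900 at H = 150, I = 10 (the
single-bias convention would give 72,450).

Training: Adam, batch 128, lr 10⁻³ dropped ×0.1 every 15 epochs, 30 epochs
at full scale; cross-entropy; everything seeded (weight init, shuffling,
dropout masks), so runs are reproducible. Implementation choices that
matter at reduced schedules: per-gate orthogonal recurrent initialization,
global-norm gradient clipping at 5, and the update-gate input bias
initialized to +1 (long memory helps, since the window statistic is an
amplitude integrated over 100 steps). Dropout defaults to 0.2: the layer
feeds a 7-unit head, and at the tens-of-epochs schedules used here p = 0.5
measurably under-trains. Hidden units are selected from
{100, 150, 200, 250, 300} by mean accuracy over subjects
(`select_hidden_units`); 150 is the package default. Training uses every
second window by default (`train_window_stride=2`): 50 %-overlapping
neighbours are near-duplicates, and halving them doubles schedule
coverage at no accuracy cost we could measure.

No class reweighting by default (rest windows dominate mildly); a
`class_weight` hook would be the first thing to add for heavily
imbalanced protocols.

## Decision layer

Smoothing averages non-overlapping triples of consecutive 50 ms posterior
frames → one output per 150 ms (a soft majority vote; a hard vote on
labels is available for comparison in the stage tables). The triple
includes the upcoming frame, so the end-to-end latency is one 100 ms
window plus 50 ms of lookahead.

Gating iterates over smoothed frames: `y = argmax`. From rest the decoder
passes through (commanding a grasp promptly is the cheap direction; a
`rest_exit_gated` switch exists for experiments). From a held grasp `c_i`,
a switch to `y` requires `p′_t(y) / p′_t(c_i) ≥ w`, with independent
thresholds for grasp→grasp and grasp→rest transitions — the state machine
is wired by transition *type*. Both operands are read from the *current*
smoothed frame, which makes the rule a proper hysteresis; mixing frames
(current candidate vs previous frame's probability) would compare
quantities from different time steps. Both thresholds default to 2.5; a
zero denominator yields ratio +∞ (switch allowed, logged). Thresholds of 0
reduce the gate to plain argmax; +∞ makes grasp states absorbing.

`optimize_thresholds` reproduces the calibration: exhaustive 9×9 grid over
{1.0, 1.5, …, 5.0}², objective = gated frame accuracy (the alternative
`fn-weighted` objective counts grasp-as-rest errors twice), ties broken
toward the smaller thresholds.

The false-negative rate is the share of true-grasp frames decoded as rest,
reported with the full 7×7 confusion matrix; it is undefined (NaN, logged)
when the truth contains no grasp frames.

## Evaluation protocol

Per subject and session: train on repetitions 1–20 (including every
normalization statistic), test on repetitions 21–30; a programmatic check
raises if any test window timestamp fails to follow the last training
window of its session. Repeats vary only seeds (classifier seed for the
baselines, GRU seed for the pipeline; splits are fixed by design).
Per-subject accuracy averages the repeats; the grand mean is the mean of
per-subject means, enforced as an exact identity. Accuracy counts rest
frames (the full 7-class problem); the stage tables also expose the FN
rate for the grasp-only view. The classical arm of pipeline comparisons
uses 300 ms windows stepped 150 ms so that both decoders are scored at the
same 150 ms decision cadence; the GRU pipeline is scored on its gated
150 ms decisions against majority-of-triple truth labels.

## Problem sizes used by the tests and the acceptance script

The suite runs the full statistical protocol at sizes chosen for a
single-CPU workflow: the fusion experiment uses the complete 8-subject ×
6-class × 30-cycle study, ten simulated studies deep; the deep-pipeline
comparison uses a 2-subject × 6-class × 30-cycle study with the reduced
GRU (100 hidden units, 10 epochs) — at these sizes the pipeline's grand
mean sits within two points of the linear SVM and gating never increases
the false-negative rate. Scaling epochs and hidden units up improves the
GRU's side of that comparison; nothing in the code is specific to the
reduced setting.

## Known limitations

* The GRU is a plain numpy implementation: correct (gradient-checked) and
  adequately fast at the documented sizes, but not a GPU framework; very
  large sweeps will be slow.
* The generator's interference magnitudes (position modulation depth,
  drift amplitude) are exposed parameters, not measured constants — no
  public quantification of these effects exists to calibrate against.
* Threshold optimization assumes the smoothed posterior stream is long
  enough to contain the transition patterns being tuned; on very short
  streams the grid surface is flat and the tie-break returns (1, 1).
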