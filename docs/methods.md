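# Methods

## Problem and pipeline

`gaitaug` studies how time-series data augmentation affects a CNN that
separates mild Parkinson's disease (PD) gait from healthy elderly (HP)
gait using tri-axial shank-worn accelerometer recordings sampled at
100 Hz. The clinical cohort this setup emulates is not publicly
available, so every experiment in this package runs on a synthetic
cohort whose statistical shape matches the emulated study: 90 subjects
(46 PD / 44 HP), one recording per shank (180 recordings), recording
lengths drawn from N(10 066, 4 232²) samples truncated below, and
per-recording sensor-mounting rotations within ±15°.

The classification pipeline is fixed:

1. **Trim** the first 8 s of every recording (unstable gait onset).
2. **Filter** each axis with a causal, single-pass 4th-order Butterworth
   bandpass, 0.25–35 Hz (removes the gravity DC component and
   high-frequency noise; gain is 1/√2 at both cutoffs).
3. **Normalize** per recording and per axis to zero mean, unit SD.
   The method is a package decision (the pipeline only specifies that
   normalization happens): recording-level statistics are used so that
   no window-level statistic can leak across the subject-level CV split.
4. **Slice** into 1024-sample windows with a 100-sample shift
   (half-open intervals, 0-based offsets, incomplete tails discarded).
5. **Augment** training windows only (never test windows), expanding the
   training set by +100% (one augmented copy per original window).
6. **Featurize** each window into a 3-channel STFT magnitude image:
   Hann window, 128-sample segments, 64-sample overlap, 128-point FFT,
   frames fully inside the window, log(1+|S|) compression → 3 × 65 × 15.
   The STFT grid is unspecified upstream and is a package decision:
   ~1.3 s segments resolve stride-band structure at 100 Hz while leaving
   15 time frames per window. Axes map to image channels (not
   concatenated), matching 2-D convolution over time–frequency.
7. **Classify** with a 4-block CNN (below); PD is the positive class.
8. **Evaluate** with subject-independent fivefold cross-validation.

## Augmentation operators

Magnitude-domain (sample values change, time indices do not):

- **Rotation (R)** — every 3-vector sample is multiplied by the
  Rodrigues rotation matrix for a random axis (uniform on the unit
  sphere, via a normalized 3-D Gaussian draw) and a random angle uniform
  on ±15°. Standard right-hand matrix
  `R = cosθ·I + sinθ·[n]ₓ + (1−cosθ)·nnᵀ`. Emulates sensor-mounting
  variation; exactly norm-preserving.
- **Jittering (J)** — i.i.d. additive Gaussian noise, σ = 0.1, per
  sample per axis.
- **Scaling (S)** — one scalar α ~ N(1, 0.2²) per window, shared by all
  samples and axes.
- **Magnitude warping (M)** — elementwise product with a smooth curve
  αₜ: an interpolating cubic spline through I = 4 evenly spaced interior
  knots plus both endpoints, all heights ~ N(1, 0.2²). Even knot
  placement is a package decision (only the count and height
  distribution are prescribed).

Time-domain (samples move to different time steps):

- **Permutation (P)** — the window is cut into N ~ U{1..5} contiguous
  near-equal segments (remainder appended to the last segment; all three
  axes cut at the same boundaries) and the segments are reordered by a
  uniform random permutation. N = 1 reproduces the window.
- **Time warping** — a positive "speed" curve is sampled exactly like a
  magnitude-warp curve (σ = 0.2 is a package default: the upstream
  description fixes the knot count but not σ, so the magnitude-warp
  value is reused), floored at 0.01 to keep the warp monotone; its
  cumulative sum, rescaled to pin both endpoints, gives τ(t), and the
  output is the linear interpolation of the input at τ(t), shared by
  all axes.
- **Cropping** — the last floor(10% · 1024) = 102 samples of every axis
  are set to zero (floor rounding is a package decision).

Mixed methods apply operators sequentially, each with independently
drawn parameters: R&S, R&J, J&P, R&S&M. Every augmented window draws a
fresh parameter set (per window, not per recording) to maximize
diversity. The full method table has 12 rows: `Nothing` (baseline), the
seven single operators, and the four compositions.

## CNN classifier and training

Four blocks of [3×3 same-padded convolution → batch normalization →
ReLU → 2×2 max-pooling], channel widths (16, 32, 64, 128), then global
average pooling and an affine map to two logits with a softmax. Pooling
clamps to size 1 along an axis whose feature map is a single cell; odd
trailing rows/columns are dropped. He-normal initialization, seeded.
The width/kernel/head choices are package decisions; only the
block structure (Conv/BN/ReLU/Maxpool ×4) is prescribed.

The network is implemented directly on numpy (im2col convolutions with
hand-written backward passes and Adam). This keeps the package
dependency-light and makes training bit-deterministic under a fixed
seed on any machine.

Training: cross-entropy, Adam (β₁ = 0.9, β₂ = 0.999), L2 weight decay
added to the gradient. Defaults are the study settings: 300 epochs,
batch 64, learning rate 1e-4, weight decay 1e-6. The sample order is
shuffled once per run and reused across epochs, so a zero learning rate
provably leaves both the parameters and the loss history unchanged.
No schedule, early stopping or validation split is used.

Hard labels are the argmax probability; an exact tie resolves to PD,
the positive class.

## Cross-validation and metrics

Folds partition **subjects**: shuffled subjects are dealt round-robin to
k = 5 folds, stratified by class (each fold's class count deviates by at
most one subject), with the deal continuing across classes so total
fold sizes also differ by at most one. Both recordings of a subject
share a fold; a leakage assertion runs on every fold. Augmentation is
applied after the split, to training windows only.

Evaluation is window-level (each 1024-sample window is one
classification decision). From TP/TN/FP/FN with PD positive:
accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = harmonic mean of precision and recall = 2TP/(2TP+FP+FN). A zero
denominator yields 0 (conservative convention). Per-fold metrics are
aggregated as the unweighted mean across folds. Methods are ranked by
mean F1, ties broken by accuracy then method name.

## Synthetic cohort model

Each subject draws: stride frequency ~ U(0.85, 1.15) Hz; per-axis
amplitudes (0.40, 0.60, 1.00) g scaled by a ±5% subject factor;
harmonic weights (1.0, 0.55, 0.30, 0.15) with ±10% jitter; stride-time
CV 0.05 ± 10%; and a mounting rotation (uniform random axis, angle
uniform on ±15°). A recording is: harmonics of the stride frequency
evaluated on a phase track built from per-cycle periods
1/f · max(0.2, N(1, CV²)); a decaying 15 Hz heel-strike burst at each
cycle start (height 0.8 × mean amplitude, mostly on the vertical axis);
additive sensor noise N(0, 0.3²) g; then the mounting rotation.

The class effect is one dial: per unit `class_effect`, PD amplitude is
reduced by 20% and PD stride-time CV increased by 20%. At
`class_effect = 0` the label has no influence on the generative
distribution at all (verified by a label-swap identity and a KS test on
per-recording RMS). Because per-recording z-scoring removes absolute
amplitude, the surviving PD signature is relative: a higher noise floor
relative to the stride harmonics and broader harmonic peaks — a
magnitude-preserving, temporally structured difference, which is the
kind of signature augmentation studies care about. Subject-level
nuisance variation (±5% amplitude, ±10% CV) is deliberately kept below
the unit class effect so the full-effect regime is separable across
subjects.

What the generator does **not** model: gyroscope channels, left/right
asymmetry or correlation beyond shared subject parameters (the two
shank recordings share parameters but have independent noise — the real
bilateral correlation structure is unknown), freezing-of-gait episodes,
turning segments, drift, and any biomechanically validated kinematics.
Passing tests on this cohort show the pipeline and protocol behave
correctly, not that the classifier would reach any particular accuracy
on clinical data.

Recording lengths are drawn from a normal truncated below at
min_length = 1824 samples (8 s trim + one full window), so every
recording yields at least one window; truncation shifts the nominal
mean/SD by ~2.6%/6.4%, which tests account for by comparing against the
truncated distribution's exact moments.

Seeding: a master seed fans out to named substreams (subject
parameters, per-recording noise, fold shuffle, per-method augmentation,
model init) via `SeedSequence`, so cohorts are bit-reproducible and
changing one stage's consumption leaves the others untouched.

## Scales

- **Study scale** (config defaults): 90 subjects, ~10 066-sample
  recordings, 300 epochs at lr 1e-4 — the emulated study conditions.
- **Desk scale** (`gaitaug.presets.desk_*`, used by the test suite and
  the reproduction script): 20 subjects/class, recording lengths
  ~N(2000, 200²), 20 epochs at lr 1e-3 and batch 64. The learning rate
  is raised with the 15× shorter schedule (fewer Adam steps → larger
  steps); the study defaults remain untouched in the config.

At desk scale the baseline (no augmentation) run has high seed-to-seed
variance — with only a few hundred training windows, individual CV
folds occasionally fail to learn — while augmented runs, with twice the
training data, are markedly more stable. This is itself the expected
small-data augmentation effect, but it means single desk-scale baseline
numbers should be read with that variance in mind.

## Numerical choices and edge cases

- Network arithmetic in float32; spline and filter arithmetic in
  float64.
- Butterworth design via second-order sections for numerical stability;
  single-pass causal filtering (zero-phase forward–backward filtering
  would double the effective attenuation order).
- The causal 0.25 Hz high-pass edge settles slowly: a DC step decays
  below 1e-3 relative only after ~20 s. Steady-state gain checks
  discard that transient.
- Time-warp speed floor 0.01 guarantees a strictly increasing τ.
- Zero-variance axes make z-scoring undefined and raise an error naming
  the axis and recording; recordings shorter than the trim raise an
  error naming the recording.
- Windows shorter than 1024 samples after trimming are silently
  dropped (a recording can contribute zero windows only if it is
  shorter than min_length, which the generator excludes).

## Known limitations

- The CNN's exact architecture beyond the 4-block pattern is a
  package choice; results are architecture-sensitive at small scales.
- Whether per-fold metrics should be pooled or averaged, and whether
  evaluation should be window- or subject-level, is ambiguous upstream;
  this package averages per-fold, window-level metrics (a subject-level
  majority vote could be added on top of `predict`).
- The ranking of augmentation methods on synthetic data does not
  predict their ranking on clinical data; only protocol-level
  properties (leakage-freedom, doubling, operator invariants,
  chance/separable behaviour) transfer.
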