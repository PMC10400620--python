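# gaitaug

Time-series data augmentation for wearable-IMU gait classification:
mild Parkinson's disease (PD) vs healthy elderly (HP) from tri-axial
shank acceleration at 100 Hz.

Deep classifiers for clinical gait data are chronically data-limited:
cohorts of a few dozen subjects, one or two walks each. `gaitaug`
implements the standard family of window-level augmentation operators
for inertial time series and a complete, leakage-safe evaluation
pipeline to compare them:

- **Magnitude-domain operators** — rotation `x'ₜ = R_n(θ)xₜ` (random
  Rodrigues rotation, axis uniform on the sphere, θ ~ U(−15°, 15°)),
  jittering `x'ₜ = xₜ + εₜ` (ε ~ N(0, 0.1²)), scaling `x'ₜ = αxₜ`
  (α ~ N(1, 0.2²)), and magnitude warping `x'ₜ = αₜxₜ` with αₜ a cubic
  spline through 4 random knots (heights ~ N(1, 0.2²)).
- **Time-domain operators** — permutation of N ~ U{1..5} equal segments,
  time warping `x'ₜ = x_τ(t)` along a smooth random monotone time map,
  and cropping (zeroing the last 10% of the window).
- **Mixed methods** — R&S, R&J, J&P, R&S&M applied sequentially.
- **Pipeline** — 8 s lead-in trim → causal 4th-order Butterworth
  bandpass (0.25–35 Hz) → per-recording z-score → 1024-sample windows
  at 100-sample shift → 3-channel STFT spectrograms (3×65×15) → a
  4-block Conv/BN/ReLU/Maxpool CNN → softmax over {PD, HP}.
- **Protocol** — subject-independent fivefold cross-validation;
  augmentation expands the training windows by +100% and never touches
  test windows; accuracy/precision/recall/F1 with PD positive, per fold
  and averaged; methods ranked by F1.

Because the emulated clinical cohort is not public, the package ships a
**synthetic gait cohort generator** (quasi-periodic stride harmonics,
per-cycle timing jitter, heel-strike transients, sensor noise, random
±15° mounting rotations) with a single `class_effect` dial from
identical classes (0) to cleanly separable classes (1). See
`docs/methods.md` for the model and its limits.

## Worked example

```python
import gaitaug as g

# a reduced cohort: 20 subjects/class, ~2000-sample recordings
cohort = g.generate_cohort(g.desk_synth_config(class_effect=1.0, master_seed=0))
print(len(cohort))                      # 80  (two shank recordings x 40 subjects)

baseline = g.run_experiment(cohort, None,
                            train_config=g.desk_train_config(seed=0), k=5, seed=0)
rotation = g.run_experiment(cohort, "R",
                            train_config=g.desk_train_config(seed=0), k=5, seed=0)
print(f"baseline  acc {baseline.accuracy:.1f}%  F1 {baseline.f1:.1f}%")
print(f"rotation  acc {rotation.accuracy:.1f}%  F1 {rotation.f1:.1f}%")
```

prints

```
80
baseline  acc 89.8%  F1 89.4%
rotation  acc 91.4%  F1 91.4%
```

i.e. on this fully separated synthetic cohort the subject-independent
CV accuracy is ~90% without augmentation, and doubling the training
windows with random rotations lifts it by ~2 points (with
`class_effect=0` the same run sits at chance, ~50%). Single desk-scale
baseline numbers vary across seeds; augmented runs are more stable.

The method comparison table (all 12 rows: `Nothing`, R, J, S, M, P,
time warping, cropping, R&S, R&J, J&P, R&S&M) runs from a config file:

```bash
gaitaug run --config experiment.yaml --out results/
gaitaug synth --out cohort_csv/ --seed 7     # cohort as CSV + manifest
```

`run` writes `fold_metrics.csv`, a ranked `summary.csv` with
delta-vs-baseline columns, per-method example plots and a
`provenance.json` (resolved config, hash, derived seeds) that makes the
run exactly reproducible.

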