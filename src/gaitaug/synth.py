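"""Synthetic shank-IMU gait cohort generator.

The clinical cohort this package's experiments emulate (90 elderly
subjects, two shank sensors each, ~100 s walks at 100 Hz) is not
publicly available, so experiments run on a synthetic stand-in: a
quasi-periodic stride model with per-cycle period jitter, heel-strike
transients, additive sensor noise and a random per-recording sensor
mounting rotation. A single ``class_effect`` dial moves the two classes
(mild PD vs healthy) apart: at 0 the class-conditional distributions
are identical, at 1 the PD class has its movement amplitude reduced by
20% and its stride-time variability increased by 20%.

The generator is a deliberately minimal biomechanical stand-in: it
exercises bandpass filtering (stride band + broadband transients),
rotation augmentation (orientation nuisance) and class separation, and
nothing more.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._rng import substream
from .core import TriaxialSeries

__all__ = [
    "SynthConfig",
    "SubjectParams",
    "generate_cohort",
    "generate_gait_series",
    "draw_lengths",
    "write_cohort",
    "load_cohort",
]

#: Fractional change in amplitude (down) and stride-time CV (up) per unit
#: of class_effect.
CLASS_EFFECT_FRACTION = 0.20

#: Per-axis base acceleration amplitudes in g (mediolateral,
#: anteroposterior, vertical-ish shank axes).
_BASE_AMPLITUDE = np.array([0.40, 0.60, 1.00])

_BASE_HARMONICS = np.array([1.0, 0.55, 0.30, 0.15])


class ConfigurationError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generation parameters.

    Defaults mirror the emulated study cohort: 100 Hz sampling,
    recording lengths ~N(10066, 4232^2) samples truncated below at
    min_length, 46 PD + 44 healthy subjects, two recordings (left and
    right shank) per subject.
    """

    n_pd_subjects: int = 46
    n_hp_subjects: int = 44
    sampling_rate: float = 100.0
    mean_length: float = 10066.0
    sd_length: float = 4232.0
    min_length: int = 1824  # trim (800) + one full window (1024)
    class_effect: float = 1.0
    mounting_angle_range: float = 15.0  # degrees, symmetric about 0
    noise_sd: float = 0.30  # additive sensor noise, g
    base_stride_time_cv: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pd_subjects < 1:
            raise ConfigurationError("n_pd_subjects must be >= 1")
        if self.n_hp_subjects < 1:
            raise ConfigurationError("n_hp_subjects must be >= 1")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.min_length < 1:
            raise ConfigurationError("min_length must be >= 1")
        if self.sd_length <= 0:
            raise ConfigurationError("sd_length must be positive")
        if not 0.0 <= self.class_effect <= 1.0:
            raise ConfigurationError("class_effect must lie in [0, 1]")
        if self.mounting_angle_range < 0:
            raise ConfigurationError("mounting_angle_range must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject gait parameters (shared by both shank recordings)."""

    subject_id: str
    label: str
    stride_frequency: float  # Hz, fundamental of the stride cycle
    amplitude: np.ndarray = field(default_factory=lambda: _BASE_AMPLITUDE.copy())
    stride_time_cv: float = 0.05
    harmonic_weights: np.ndarray = field(default_factory=lambda: _BASE_HARMONICS.copy())
    rotation_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    rotation_angle_deg: float = 0.0
    noise_sd: float = 0.30
    transient_scale: float = 0.8  # heel-strike burst height relative to mean amplitude

    def __post_init__(self) -> None:
        if not 0.5 < self.stride_frequency < 1.5:
            raise ConfigurationError(
                f"stride_frequency must lie in (0.5, 1.5) Hz, got {self.stride_frequency}"
            )
        if self.stride_time_cv < 0:
            raise ConfigurationError("stride_time_cv must be >= 0")
        amp = np.asarray(self.amplitude, dtype=float)
        if np.any(amp < 0):
            raise ConfigurationError("amplitude must be non-negative")
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "harmonic_weights", np.asarray(self.harmonic_weights, dtype=float))
        axis = np.asarray(self.rotation_axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ConfigurationError("rotation_axis must be non-zero")
        object.__setattr__(self, "rotation_axis", axis / n)


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation by angle_deg about the unit vector axis."""
    n = np.asarray(axis, dtype=float)
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    K = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(n, n)


def _draw_subject(cfg: SynthConfig, subject_index: int, label: str) -> SubjectParams:
    rng = substream(cfg.master_seed, "subject", subject_index)
    effect = cfg.class_effect if label == "PD" else 0.0

    stride_frequency = rng.uniform(0.85, 1.15)
    # Subject-level nuisance variation is kept smaller than the unit
    # class effect so a full-effect cohort is separable across subjects.
    amp_factor = rng.uniform(0.95, 1.05)
    amplitude = _BASE_AMPLITUDE * amp_factor * (1.0 - CLASS_EFFECT_FRACTION * effect)
    stride_time_cv = (
        cfg.base_stride_time_cv * rng.uniform(0.9, 1.1) * (1.0 + CLASS_EFFECT_FRACTION * effect)
    )
    harmonics = _BASE_HARMONICS * rng.uniform(0.9, 1.1, size=_BASE_HARMONICS.shape)

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-cfg.mounting_angle_range, cfg.mounting_angle_range)

    return SubjectParams(
        subject_id=f"S{subject_index:03d}",
        label=label,
        stride_frequency=stride_frequency,
        amplitude=amplitude,
        stride_time_cv=stride_time_cv,
        harmonic_weights=harmonics,
        rotation_axis=axis,
        rotation_angle_deg=angle,
        noise_sd=cfg.noise_sd,
    )


def draw_lengths(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n recording lengths from N(mean, sd^2) truncated below at min_length."""
    a = (cfg.min_length - cfg.mean_length) / cfg.sd_length
    x = truncnorm.rvs(a, np.inf, loc=cfg.mean_length, scale=cfg.sd_length, size=n, random_state=rng)
    return np.maximum(np.round(x).astype(int), cfg.min_length)


def generate_gait_series(
    params: SubjectParams, length: int, seed: int, *, sampling_rate: float = 100.0,
    side: str = "left",
) -> TriaxialSeries:
    """Generate one recording from per-subject gait parameters.

    The model: stride cycles with durations 1/f * max(0.2, N(1, cv^2));
    within each cycle, a harmonic series of the stride frequency with
    fixed per-axis phase offsets; a decaying heel-strike oscillation at
    every cycle start; i.i.d. Gaussian sensor noise; finally the whole
    3-vector stream is rotated by the subject's mounting rotation.
    """
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    t = np.arange(length) / fs

    # Instantaneous phase: piecewise-linear through jittered cycle periods.
    mean_period = 1.0 / params.stride_frequency
    n_cycles = int(np.ceil(length / fs / mean_period)) + 3
    periods = mean_period * np.maximum(0.2, rng.normal(1.0, params.stride_time_cv, size=n_cycles))
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    phase = np.interp(t, boundaries, np.arange(n_cycles + 1, dtype=float))

    axis_phases = np.array([0.0, 0.35, 0.60])  # fixed per-axis phase lags (cycles)
    signal = np.zeros((length, 3))
    for h, w in enumerate(params.harmonic_weights, start=1):
        arg = 2 * np.pi * h * (phase[:, None] - axis_phases[None, :])
        signal += w * np.sin(arg)
    signal *= params.amplitude[None, :]

    # Heel-strike transients: short decaying 15 Hz burst at each cycle start.
    if params.transient_scale > 0:
        strike_times = boundaries[boundaries < t[-1] + mean_period]
        burst_amp = params.transient_scale * float(np.mean(params.amplitude))
        tau, f_burst = 0.05, 15.0
        for ts in strike_times:
            i0 = int(np.ceil(ts * fs))
            i1 = min(length, i0 + int(0.25 * fs))
            if i0 >= length:
                continue
            dt = t[i0:i1] - ts
            burst = burst_amp * np.exp(-dt / tau) * np.sin(2 * np.pi * f_burst * dt)
            signal[i0:i1, 2] += burst
            signal[i0:i1, 0] += 0.3 * burst

    if params.noise_sd > 0:
        signal = signal + rng.normal(0.0, params.noise_sd, size=signal.shape)

    R = _rotation_matrix(params.rotation_axis, params.rotation_angle_deg)
    signal = signal @ R.T

    return TriaxialSeries(
        values=signal,
        sampling_rate=fs,
        subject_id=params.subject_id,
        side=side,
        label=params.label,
    )


def generate_cohort(cfg: SynthConfig) -> list[TriaxialSeries]:
    """Generate the full cohort: left + right recording per subject.

    Deterministic in cfg.master_seed. Subject labels are assigned by
    index (PD first), but with class_effect = 0 the label has no effect
    on the generated values.
    """
    n_total = cfg.n_pd_subjects + cfg.n_hp_subjects
    length_rng = substream(cfg.master_seed, "lengths")
    lengths = draw_lengths(cfg, 2 * n_total, length_rng)

    cohort: list[TriaxialSeries] = []
    for i in range(n_total):
        label = "PD" if i < cfg.n_pd_subjects else "HP"
        params = _draw_subject(cfg, i, label)
        for j, side in enumerate(("left", "right")):
            seed = int(substream(cfg.master_seed, "recording", i, side).integers(0, 2**31))
            series = generate_gait_series(
                params, int(lengths[2 * i + j]), seed,
                sampling_rate=cfg.sampling_rate, side=side,
            )
            cohort.append(series)
    return cohort


# ---------------------------------------------------------------------------
# Cohort on-disk format: one CSV per recording + JSON sidecar + manifest.

def write_cohort(cohort: list[TriaxialSeries], out_dir: str | Path) -> Path:
    """Write recordings as CSV (time_s, ax, ay, az) with JSON sidecars.

    Returns the path of the manifest CSV (file, subject_id, side, label).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        stem = rec.recording_id
        t = np.arange(rec.n_samples) / rec.sampling_rate
        df = pd.DataFrame(
            {"time_s": t, "ax": rec.values[:, 0], "ay": rec.values[:, 1], "az": rec.values[:, 2]}
        )
        df.to_csv(out / f"{stem}.csv", index=False, float_format="%.6f")
        meta = {
            "subject_id": rec.subject_id,
            "side": rec.side,
            "label": rec.label,
            "sampling_rate": rec.sampling_rate,
            "n_samples": rec.n_samples,
        }
        (out / f"{stem}.json").write_text(json.dumps(meta, indent=2))
        rows.append({"file": f"{stem}.csv", "subject_id": rec.subject_id,
                     "side": rec.side, "label": rec.label})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[TriaxialSeries]:
    """Load a cohort written by write_cohort."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    cohort = []
    for row in manifest.itertuples():
        meta = json.loads((base / row.file).with_suffix(".json").read_text())
        df = pd.read_csv(base / row.file)
        cohort.append(
            TriaxialSeries(
                values=df[["ax", "ay", "az"]].to_numpy(),
                sampling_rate=float(meta["sampling_rate"]),
                subject_id=str(row.subject_id),
                side=str(row.side),
                label=str(row.label),
            )
        )
    return cohort
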