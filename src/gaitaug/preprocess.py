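"""Recording preprocessing: trim, bandpass filter, normalize, slice.

The fixed pipeline order is trim -> filter -> normalize -> slice.
Filtering is a single-pass causal 4th-order Butterworth bandpass
(0.25-35 Hz); normalization is a per-recording, per-axis z-score, so
window-level statistics never leak across the train/test split; slicing
cuts 1024-sample windows every 100 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import WINDOW_LENGTH, WINDOW_SHIFT, TriaxialSeries, Window

__all__ = [
    "FilterSpec",
    "bandpass_filter",
    "filter_gain",
    "trim_lead_in",
    "normalize",
    "slice_windows",
    "preprocess_recording",
]

DEFAULT_TRIM_SECONDS = 8.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass design: order 4, passband 0.25-35 Hz."""

    order: int = 4
    low_cut: float = 0.25
    high_cut: float = 35.0

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not 0 < self.low_cut < self.high_cut < nyquist:
            raise ValueError(
                f"cutoffs must satisfy 0 < low ({self.low_cut}) < high "
                f"({self.high_cut}) < Nyquist ({nyquist})"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def sos(self, sampling_rate: float) -> np.ndarray:
        self.validate(sampling_rate)
        return signal.butter(
            self.order, [self.low_cut, self.high_cut], btype="bandpass",
            fs=sampling_rate, output="sos",
        )


def filter_gain(spec: FilterSpec, sampling_rate: float, freqs_hz) -> np.ndarray:
    """Magnitude response of the designed filter at the given frequencies."""
    sos = spec.sos(sampling_rate)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs_hz, dtype=float)),
                           fs=sampling_rate)
    return np.abs(h)


def bandpass_filter(series: TriaxialSeries, spec: FilterSpec = FilterSpec()) -> TriaxialSeries:
    """Causal single-pass bandpass of each axis; length preserved."""
    sos = spec.sos(series.sampling_rate)
    if series.n_samples <= 3 * spec.order:
        raise ValueError(
            f"recording {series.recording_id} too short ({series.n_samples} samples) "
            f"for an order-{spec.order} filter"
        )
    filtered = signal.sosfilt(sos, series.values, axis=0)
    return series.with_values(filtered)


def trim_lead_in(series: TriaxialSeries, seconds: float = DEFAULT_TRIM_SECONDS) -> TriaxialSeries:
    """Drop the initial unstable-gait segment (default 8 s)."""
    n_trim = int(round(seconds * series.sampling_rate))
    if series.n_samples <= n_trim:
        raise ValueError(
            f"recording {series.recording_id} has {series.n_samples} samples, "
            f"shorter than the {n_trim}-sample lead-in trim"
        )
    return series.with_values(series.values[n_trim:])


def normalize(series: TriaxialSeries) -> TriaxialSeries:
    """Per-recording, per-axis z-score (mean 0, SD 1 per axis)."""
    v = series.values
    mean = v.mean(axis=0)
    sd = v.std(axis=0)
    for axis_idx, axis_name in enumerate("xyz"):
        if sd[axis_idx] == 0:
            raise ValueError(
                f"axis {axis_name} of recording {series.recording_id} has zero variance"
            )
    return series.with_values((v - mean) / sd)


def slice_windows(
    series: TriaxialSeries,
    window: int = WINDOW_LENGTH,
    shift: int = WINDOW_SHIFT,
) -> list[Window]:
    """Cut half-open windows [k*shift, k*shift + window) while they fit.

    A recording shorter than one window yields an empty list; the
    incomplete tail is discarded.
    """
    if window < 1 or shift < 1:
        raise ValueError("window and shift must be >= 1")
    T = series.n_samples
    out = []
    for offset in range(0, T - window + 1, shift):
        out.append(
            Window(
                values=series.values[offset : offset + window],
                subject_id=series.subject_id,
                side=series.side,
                label=series.label,
                source_offset=offset,
            )
        )
    return out


def preprocess_recording(
    series: TriaxialSeries,
    spec: FilterSpec = FilterSpec(),
    trim_seconds: float = DEFAULT_TRIM_SECONDS,
    window: int = WINDOW_LENGTH,
    shift: int = WINDOW_SHIFT,
) -> list[Window]:
    """Full fixed-order pipeline: trim -> filter -> normalize -> slice."""
    trimmed = trim_lead_in(series, trim_seconds)
    filtered = bandpass_filter(trimmed, spec)
    normed = normalize(filtered)
    return slice_windows(normed, window, shift)
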