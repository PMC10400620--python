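"""Window -> 3-channel STFT magnitude spectrogram.

Each axis of a 1024-sample window becomes one channel of a
time-frequency image: Hann-windowed STFT with 128-sample segments and
64-sample overlap (no padding, frames fully inside the window), then a
log(1 + |S|) magnitude compression. Defaults give a 3 x 65 x 15 tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import Window

__all__ = ["StftParams", "SpectrogramTensor", "stft_spectrogram", "featurize"]


@dataclass(frozen=True)
class StftParams:
    segment_length: int = 128
    overlap: int = 64
    fft_length: int = 128

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.segment_length <= self.fft_length:
            raise ValueError(
                "require 0 <= overlap < segment_length <= fft_length, got "
                f"overlap={self.overlap}, segment={self.segment_length}, fft={self.fft_length}"
            )

    @property
    def hop(self) -> int:
        return self.segment_length - self.overlap

    def n_frames(self, n_samples: int) -> int:
        return (n_samples - self.segment_length) // self.hop + 1

    @property
    def n_bins(self) -> int:
        return self.fft_length // 2 + 1


@dataclass(frozen=True)
class SpectrogramTensor:
    """log1p-magnitude spectrogram, shape (3 channels, F bins, M frames)."""

    values: np.ndarray
    label: str
    subject_id: str
    side: str
    source_offset: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != 3:
            raise ValueError(f"spectrogram tensor must be (3, F, M), got {v.shape}")
        object.__setattr__(self, "values", v)


def stft_spectrogram(w: Window, p: StftParams = StftParams(),
                     sampling_rate: float = 100.0) -> SpectrogramTensor:
    """Per-axis magnitude spectrogram; channels ordered (x, y, z).

    Deterministic: no randomness anywhere in featurization.
    """
    n = w.values.shape[0]
    if n < p.segment_length:
        raise ValueError(f"window length {n} < STFT segment length {p.segment_length}")
    _, _, Z = signal.stft(
        w.values, fs=sampling_rate, window="hann",
        nperseg=p.segment_length, noverlap=p.overlap, nfft=p.fft_length,
        boundary=None, padded=False, axis=0,
    )
    # Z has shape (F, 3, M); reorder to (3, F, M).
    mag = np.log1p(np.abs(np.moveaxis(Z, 1, 0)))
    return SpectrogramTensor(
        values=mag, label=w.label, subject_id=w.subject_id,
        side=w.side, source_offset=w.source_offset,
    )


def featurize(windows: list[Window], p: StftParams = StftParams(),
              sampling_rate: float = 100.0) -> np.ndarray:
    """Stack spectrograms of many windows into an (N, 3, F, M) array."""
    return np.stack([stft_spectrogram(w, p, sampling_rate).values for w in windows])
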