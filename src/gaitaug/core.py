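"""Core containers shared across the pipeline.

A recording is a tri-axial shank acceleration stream; the unit of
classification is a fixed-length window cut from a preprocessed
recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Class labels. PD (mild Parkinson's disease) is the positive class
#: throughout; HP is the healthy elderly participant group.
LABELS = ("PD", "HP")
POSITIVE_LABEL = "PD"

WINDOW_LENGTH = 1024
WINDOW_SHIFT = 100


@dataclass(frozen=True)
class TriaxialSeries:
    """One recording of 3-axis acceleration.

    values has shape (T, 3): columns are the x/y/z sensor axes in g.
    """

    values: np.ndarray
    sampling_rate: float
    subject_id: str
    side: str  # "left" | "right"
    label: str  # "PD" | "HP"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"values must be (T, 3), got {v.shape}")
        if v.shape[0] < 1:
            raise ValueError("series must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in recording {self.subject_id}/{self.side}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}_{self.side}"

    def with_values(self, values: np.ndarray) -> "TriaxialSeries":
        return replace(self, values=values)


@dataclass(frozen=True)
class Window:
    """A 1024 x 3 slice of a preprocessed recording."""

    values: np.ndarray
    subject_id: str
    side: str
    label: str
    source_offset: int = 0
    augmented: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (WINDOW_LENGTH, 3):
            raise ValueError(f"window must be ({WINDOW_LENGTH}, 3), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite values in window")
        object.__setattr__(self, "values", v)

    def with_values(self, values: np.ndarray, *, augmented: bool = True) -> "Window":
        """Same provenance/label, new sample values (an augmented copy)."""
        return replace(self, values=np.asarray(values, dtype=float), augmented=augmented)
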