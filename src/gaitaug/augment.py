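"""Time-series augmentation operators for windowed tri-axial signals.

Magnitude-domain operators change sample values in place on the time
axis: rotation (random 3-D rotation of every acceleration vector),
jittering (additive Gaussian noise), scaling (one random scalar per
window), magnitude warping (elementwise product with a smooth random
cubic-spline curve). Time-domain operators displace samples: permutation
(shuffle contiguous segments), time warping (resample along a smooth
random monotone time map), cropping (zero the final 10%). Mixed methods
apply operators sequentially.

Operator hyperparameters follow the study defaults: rotation axis
uniform on the sphere with angle uniform on +/-15 deg, jitter sigma 0.1,
scaling sigma 0.2, warp curves from I = 4 interior knots with heights
~ N(1, 0.2^2), permutation segment count uniform on {1..5}, crop
fraction 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._rng import substream
from .core import WINDOW_LENGTH, Window

__all__ = [
    "RotationParams",
    "JitterParams",
    "ScaleParams",
    "WarpCurve",
    "PermutationParams",
    "AugmentationSpec",
    "rotation_matrix",
    "rotate",
    "jitter",
    "scale",
    "magnitude_warp",
    "permute",
    "time_warp",
    "crop",
    "compose",
    "expand_training_set",
    "METHOD_TABLE",
    "method_spec",
]

CROP_FRACTION = 0.10
SPEED_FLOOR = 0.01


@dataclass(frozen=True)
class RotationParams:
    axis: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError(f"rotation axis must be a unit vector, |n| = {np.linalg.norm(a)}")
        object.__setattr__(self, "axis", a)

    @staticmethod
    def sample(rng: np.random.Generator, angle_range: float = 15.0) -> "RotationParams":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        return RotationParams(axis=axis, angle_deg=float(rng.uniform(-angle_range, angle_range)))


@dataclass(frozen=True)
class JitterParams:
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("jitter sigma must be >= 0")


@dataclass(frozen=True)
class ScaleParams:
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("scale sigma must be >= 0")


@dataclass(frozen=True)
class WarpCurve:
    """Smooth random curve through I interior knots plus two endpoints.

    Knot positions are evenly spaced over the window; knot and endpoint
    heights are drawn from N(1, sigma^2). Evaluated with an
    interpolating cubic spline at every sample index.
    """

    heights: np.ndarray  # length n_knots + 2, including both endpoints
    length: int = WINDOW_LENGTH

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 1 or h.size < 2:
            raise ValueError("heights must be a 1-D array of at least 2 values")
        object.__setattr__(self, "heights", h)

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0, self.length - 1, self.heights.size)

    def evaluate(self) -> np.ndarray:
        spline = CubicSpline(self.positions, self.heights)
        return spline(np.arange(self.length))

    @staticmethod
    def sample(
        rng: np.random.Generator, n_knots: int = 4, sigma: float = 0.2,
        length: int = WINDOW_LENGTH,
    ) -> "WarpCurve":
        heights = rng.normal(1.0, sigma, size=n_knots + 2)
        return WarpCurve(heights=heights, length=length)


@dataclass(frozen=True)
class PermutationParams:
    n_segments: int
    order: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.n_segments <= 5:
            raise ValueError("segment count must lie in {1..5}")
        if sorted(self.order) != list(range(self.n_segments)):
            raise ValueError("order must be a permutation of the segments")

    @staticmethod
    def sample(rng: np.random.Generator, max_segments: int = 5) -> "PermutationParams":
        n = int(rng.integers(1, max_segments + 1))
        return PermutationParams(n_segments=n, order=tuple(int(i) for i in rng.permutation(n)))


# ---------------------------------------------------------------------------
# Operators. Each maps a Window to a new Window with identical metadata.

def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Standard Rodrigues rotation matrix, right-hand convention."""
    n = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValueError("rotation axis must be a unit vector")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    K = np.array([[0.0, -n[2], n[1]], [n[2], 0.0, -n[0]], [-n[1], n[0], 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(n, n)


def rotate(w: Window, p: RotationParams) -> Window:
    R = rotation_matrix(p.axis, p.angle_deg)
    return w.with_values(w.values @ R.T)


def jitter(w: Window, p: JitterParams, rng: np.random.Generator) -> Window:
    noise = rng.normal(0.0, p.sigma, size=w.values.shape)
    return w.with_values(w.values + noise)


def scale(w: Window, p: ScaleParams, rng: np.random.Generator) -> Window:
    alpha = rng.normal(1.0, p.sigma)
    return w.with_values(alpha * w.values)


def magnitude_warp(w: Window, curve: WarpCurve) -> Window:
    if curve.length != w.values.shape[0]:
        raise ValueError(
            f"warp curve length {curve.length} != window length {w.values.shape[0]}"
        )
    alpha_t = curve.evaluate()
    return w.with_values(w.values * alpha_t[:, None])


def permute(w: Window, p: PermutationParams) -> Window:
    """Reorder N near-equal contiguous segments; axes are cut jointly.

    When the length is not divisible by N the remainder goes to the
    last segment.
    """
    T = w.values.shape[0]
    seg = T // p.n_segments
    bounds = [(i * seg, (i + 1) * seg if i < p.n_segments - 1 else T)
              for i in range(p.n_segments)]
    pieces = [w.values[bounds[i][0] : bounds[i][1]] for i in p.order]
    return w.with_values(np.concatenate(pieces, axis=0))


def time_warp(w: Window, curve: WarpCurve) -> Window:
    """Resample along tau(t), the normalised cumulative sum of a smooth
    positive speed curve; endpoints are pinned so tau(0) = 0 and
    tau(T-1) = T-1; all three axes share tau."""
    T = w.values.shape[0]
    if curve.length != T:
        raise ValueError(f"warp curve length {curve.length} != window length {T}")
    speed = np.maximum(curve.evaluate(), SPEED_FLOOR)
    if np.all(curve.evaluate() <= SPEED_FLOOR):
        raise ValueError("degenerate time-warp curve: speed at or below floor everywhere")
    c = np.cumsum(speed)
    tau = (c - c[0]) / (c[-1] - c[0]) * (T - 1)
    t = np.arange(T)
    warped = np.column_stack([np.interp(tau, t, w.values[:, k]) for k in range(3)])
    return w.with_values(warped)


def crop(w: Window) -> Window:
    """Zero the last floor(10% of T) samples of every axis."""
    T = w.values.shape[0]
    n_zero = int(np.floor(CROP_FRACTION * T))
    out = w.values.copy()
    if n_zero > 0:
        out[T - n_zero :] = 0.0
    return w.with_values(out)


# ---------------------------------------------------------------------------
# Random application, composition and training-set expansion.

_OPERATOR_NAMES = (
    "rotation", "jittering", "scaling", "magnitude_warp",
    "permutation", "time_warp", "cropping",
)


@dataclass(frozen=True)
class AugmentationSpec:
    """An ordered operator composition plus the expansion factor.

    operators: names from {rotation, jittering, scaling, magnitude_warp,
    permutation, time_warp, cropping}, applied left to right with
    independently sampled parameters per augmented window.
    factor: fraction of extra windows (1.0 = +100%, doubling).
    """

    operators: tuple[str, ...]
    factor: float = 1.0
    rotation_range_deg: float = 15.0
    jitter_sigma: float = 0.1
    scale_sigma: float = 0.2
    warp_sigma: float = 0.2
    warp_knots: int = 4
    max_segments: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "operators", tuple(self.operators))
        for name in self.operators:
            if name not in _OPERATOR_NAMES:
                raise ValueError(
                    f"unknown operator {name!r}; expected one of {_OPERATOR_NAMES}"
                )
        if self.factor < 0:
            raise ValueError("augmentation factor must be >= 0")


def _apply_operator(name: str, w: Window, spec: AugmentationSpec,
                    rng: np.random.Generator) -> Window:
    if name == "rotation":
        return rotate(w, RotationParams.sample(rng, spec.rotation_range_deg))
    if name == "jittering":
        return jitter(w, JitterParams(spec.jitter_sigma), rng)
    if name == "scaling":
        return scale(w, ScaleParams(spec.scale_sigma), rng)
    if name == "magnitude_warp":
        return magnitude_warp(
            w, WarpCurve.sample(rng, spec.warp_knots, spec.warp_sigma, w.values.shape[0])
        )
    if name == "permutation":
        return permute(w, PermutationParams.sample(rng, spec.max_segments))
    if name == "time_warp":
        return time_warp(
            w, WarpCurve.sample(rng, spec.warp_knots, spec.warp_sigma, w.values.shape[0])
        )
    if name == "cropping":
        return crop(w)
    raise ValueError(f"unknown operator {name!r}")


def compose(spec: AugmentationSpec, w: Window, seed: int) -> Window:
    """Apply the configured operators left-to-right with fresh random
    parameters drawn from per-operator substreams of ``seed``."""
    if not spec.operators:
        raise ValueError("operator list must be non-empty")
    out = w
    for k, name in enumerate(spec.operators):
        rng = substream(seed, "op", k, name)
        out = _apply_operator(name, out, spec, rng)
    return out


def expand_training_set(windows: list[Window], spec: AugmentationSpec) -> list[Window]:
    """Return originals plus factor x |windows| augmented copies.

    At the default +100% factor the training set exactly doubles; every
    augmented copy keeps its source window's label and provenance. Test
    windows must never pass through this function.
    """
    if not windows:
        raise ValueError("cannot expand an empty training set")
    n = len(windows)
    n_aug = int(round(spec.factor * n))
    out = list(windows)
    for j in range(n_aug):
        src = windows[j % n]
        seed = int(substream(spec.seed, "window", j).integers(0, 2**31))
        out.append(compose(spec, src, seed))
    return out


#: The study's method table: label -> operator composition (None = baseline).
METHOD_TABLE: dict[str, tuple[str, ...] | None] = {
    "Nothing": None,
    "R": ("rotation",),
    "J": ("jittering",),
    "S": ("scaling",),
    "M": ("magnitude_warp",),
    "P": ("permutation",),
    "time warping": ("time_warp",),
    "cropping": ("cropping",),
    "R&S": ("rotation", "scaling"),
    "R&J": ("rotation", "jittering"),
    "J&P": ("jittering", "permutation"),
    "R&S&M": ("rotation", "scaling", "magnitude_warp"),
}


def method_spec(name: str, factor: float = 1.0, seed: int = 0) -> AugmentationSpec | None:
    """Resolve a method label from the study table to an AugmentationSpec."""
    if name not in METHOD_TABLE:
        raise ValueError(f"unknown method {name!r}; expected one of {sorted(METHOD_TABLE)}")
    ops = METHOD_TABLE[name]
    if ops is None:
        return None
    return AugmentationSpec(operators=ops, factor=factor, seed=seed)
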