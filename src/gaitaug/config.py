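"""Experiment configuration and the reproducible end-to-end driver.

A single YAML/JSON file describes a whole experiment: cohort
generation, filtering, windowing, STFT, model, training, the list of
augmentation methods, and a master seed. Unknown keys are rejected.
Every run writes its fully resolved configuration, derived seeds and a
config hash alongside its results so it can be reconstructed exactly.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata as _im
from pathlib import Path

import pydantic
import yaml

from ._rng import child_seed
from .augment import METHOD_TABLE
from .core import WINDOW_LENGTH, WINDOW_SHIFT
from .evaluate import rank_methods, run_method_table
from .features import StftParams
from .model import ModelConfig, TrainConfig
from .preprocess import DEFAULT_TRIM_SECONDS, FilterSpec
from .synth import SynthConfig, generate_cohort, load_cohort

__all__ = ["ExperimentConfig", "ConfigError", "load_config", "run_all"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class _Block(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class SynthBlock(_Block):
    n_pd_subjects: int = 46
    n_hp_subjects: int = 44
    sampling_rate: float = 100.0
    mean_length: float = 10066.0
    sd_length: float = 4232.0
    min_length: int = 1824
    class_effect: float = 1.0
    mounting_angle_range: float = 15.0
    noise_sd: float = 0.30
    base_stride_time_cv: float = 0.05


class FilterBlock(_Block):
    order: int = 4
    low_cut: float = 0.25
    high_cut: float = 35.0


class WindowBlock(_Block):
    length: int = WINDOW_LENGTH
    shift: int = WINDOW_SHIFT
    trim_seconds: float = DEFAULT_TRIM_SECONDS


class StftBlock(_Block):
    segment_length: int = 128
    overlap: int = 64
    fft_length: int = 128


class ModelBlock(_Block):
    channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3


class TrainBlock(_Block):
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 1e-6


class AugmentBlock(_Block):
    rotation_range_deg: float = 15.0
    jitter_sigma: float = 0.1
    scale_sigma: float = 0.2
    warp_sigma: float = 0.2
    warp_knots: int = 4
    max_segments: int = 5
    factor: float = 1.0  # +100%


class ExperimentConfig(_Block):
    """Fully resolved experiment description (defaults = study values)."""

    synth: SynthBlock = SynthBlock()
    cohort_manifest: str | None = None  # load instead of generating
    filter: FilterBlock = FilterBlock()
    window: WindowBlock = WindowBlock()
    stft: StftBlock = StftBlock()
    model: ModelBlock = ModelBlock()
    train: TrainBlock = TrainBlock()
    augment: AugmentBlock = AugmentBlock()
    methods: list[str] = pydantic.Field(default_factory=lambda: list(METHOD_TABLE))
    k_folds: int = 5
    master_seed: int = 0

    @pydantic.field_validator("methods")
    @classmethod
    def _known_methods(cls, v: list[str]) -> list[str]:
        for m in v:
            if m not in METHOD_TABLE:
                raise ValueError(f"unknown method {m!r}; expected one of {sorted(METHOD_TABLE)}")
        return v

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            master_seed=child_seed(self.master_seed, "cohort"),
            **self.synth.model_dump(),
        )

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(**self.filter.model_dump())

    def stft_params(self) -> StftParams:
        return StftParams(**self.stft.model_dump())

    def model_config_obj(self) -> ModelConfig:
        return ModelConfig(**self.model.model_dump())

    def train_config(self) -> TrainConfig:
        return TrainConfig(**self.train.model_dump())

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Load YAML/JSON config; missing keys take the study defaults.

    Unknown keys, type mismatches and invariant violations raise a
    ConfigError naming the offending field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if overrides:
        data = {**data, **overrides}
    try:
        return ExperimentConfig(**data)
    except pydantic.ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _plot_method_examples(cohort, cfg: ExperimentConfig, out_dir: Path) -> None:
    """One before/after figure per method for a sample window."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .augment import compose, method_spec
    from .preprocess import preprocess_recording

    windows = preprocess_recording(cohort[0], cfg.filter_spec())
    if not windows:
        return
    w = windows[0]
    for name in cfg.methods:
        spec = method_spec(name, factor=cfg.augment.factor,
                          seed=child_seed(cfg.master_seed, "plot", name))
        fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
        axes[0].plot(w.values[:, 2], lw=0.6)
        axes[0].set_title("original (z axis)")
        if spec is None:
            axes[1].plot(w.values[:, 2], lw=0.6)
        else:
            out = compose(spec, w, seed=child_seed(cfg.master_seed, "plot-window", name))
            axes[1].plot(out.values[:, 2], lw=0.6, color="tab:orange")
        axes[1].set_title(name)
        fig.tight_layout()
        fig.savefig(out_dir / f"example_{name.replace('&', '_').replace(' ', '_')}.png", dpi=90)
        plt.close(fig)


def run_all(cfg: ExperimentConfig, out_dir: str | Path, *, plots: bool = True) -> Path:
    """Generate/load the cohort, run every configured method, write results.

    Outputs under out_dir: per-fold metrics CSV, ranked summary CSV,
    per-method example plots, and provenance.json. Returns out_dir.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.cohort_manifest is not None:
        cohort = load_cohort(cfg.cohort_manifest)
    else:
        cohort = generate_cohort(cfg.synth_config())

    reports = run_method_table(
        cohort, cfg.methods,
        filter_spec=cfg.filter_spec(),
        stft_params=cfg.stft_params(),
        model_config=cfg.model_config_obj(),
        train_config=cfg.train_config(),
        k=cfg.k_folds,
        seed=child_seed(cfg.master_seed, "experiment"),
        augmentation_factor=cfg.augment.factor,
    )

    fold_rows = []
    for r in reports:
        for i, f in enumerate(r.folds):
            fold_rows.append(
                {"method": r.method, "fold": i, "tp": f.counts.tp, "tn": f.counts.tn,
                 "fp": f.counts.fp, "fn": f.counts.fn, "accuracy": round(f.accuracy, 4),
                 "precision": round(f.precision, 4), "recall": round(f.recall, 4),
                 "f1": round(f.f1, 4)}
            )
    import pandas as pd

    pd.DataFrame(fold_rows).to_csv(out / "fold_metrics.csv", index=False)

    summary = rank_methods(reports) if len(reports) >= 2 else None
    if summary is not None:
        summary.round(4).to_csv(out / "summary.csv")
    else:
        r = reports[0]
        pd.DataFrame(
            [{"method": r.method, "accuracy": r.accuracy, "precision": r.precision,
              "recall": r.recall, "f1": r.f1}]
        ).round(4).to_csv(out / "summary.csv", index=False)

    if plots:
        _plot_method_examples(cohort, cfg, out)

    try:
        version = _im.version("gaitaug")
    except _im.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    provenance = {
        "config": cfg.model_dump(),
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "derived_seeds": {
            "cohort": child_seed(cfg.master_seed, "cohort"),
            "experiment": child_seed(cfg.master_seed, "experiment"),
        },
        "n_recordings": len(cohort),
        "package_version": version,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return out
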