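"""Preset experiment scales.

``study_*`` presets mirror the emulated clinical study (90 subjects,
~10,066-sample recordings, 300 training epochs at learning rate 1e-4).
``desk_*`` presets are the package's reduced protocol for laptop/CI
runs: 20 subjects per class, ~2,000-sample recordings, 20 epochs at
learning rate 1e-3 (the shorter schedule takes a proportionally larger
Adam step). The desk scale is what the test-suite and the bundled
reproduction script use.
"""

from __future__ import annotations

from .model import TrainConfig
from .synth import SynthConfig

__all__ = [
    "study_synth_config",
    "study_train_config",
    "desk_synth_config",
    "desk_train_config",
]


def study_synth_config(class_effect: float = 1.0, master_seed: int = 0) -> SynthConfig:
    """The emulated study cohort: 46 PD + 44 HP subjects, two shank
    recordings each, lengths ~N(10066, 4232^2) at 100 Hz."""
    return SynthConfig(class_effect=class_effect, master_seed=master_seed)


def study_train_config(seed: int = 0) -> TrainConfig:
    """The study's training settings: 300 epochs, batch 64, Adam with
    learning rate 1e-4 and weight decay 1e-6."""
    return TrainConfig(seed=seed)


def desk_synth_config(
    class_effect: float = 1.0,
    master_seed: int = 0,
    n_per_class: int = 20,
) -> SynthConfig:
    """Reduced cohort: n_per_class subjects per class, ~2,000-sample
    recordings (a handful of windows each)."""
    return SynthConfig(
        n_pd_subjects=n_per_class,
        n_hp_subjects=n_per_class,
        mean_length=2000.0,
        sd_length=200.0,
        class_effect=class_effect,
        master_seed=master_seed,
    )


def desk_train_config(seed: int = 0, epochs: int = 20) -> TrainConfig:
    """Short training schedule for reduced runs."""
    return TrainConfig(epochs=epochs, batch_size=64, learning_rate=1e-3,
                       weight_decay=1e-6, seed=seed)
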