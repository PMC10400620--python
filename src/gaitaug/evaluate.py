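"""Subject-independent fivefold cross-validation and evaluation metrics.

Folds partition subjects, never recordings or windows, so both shank
recordings of a subject (and all their windows) land on the same side
of every train/test split. Metrics are confusion-matrix based with PD
as the positive class: accuracy, precision, recall and F1 (harmonic
mean of precision and recall), reported per fold and as the unweighted
mean across folds. Zero-denominator precision/recall/F1 are reported
as 0 by convention.

Classification is window-level: each 1024-sample window is scored
independently, matching the per-window CNN input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_seed, substream
from .augment import METHOD_TABLE, AugmentationSpec, expand_training_set, method_spec
from .core import POSITIVE_LABEL, TriaxialSeries, Window
from .features import StftParams, featurize
from .model import CnnClassifier, ModelConfig, TrainConfig, build_model, predict, train
from .preprocess import FilterSpec, preprocess_recording

__all__ = [
    "FoldAssignment",
    "ConfusionCounts",
    "MetricsReport",
    "assign_folds",
    "confusion_counts",
    "metrics",
    "run_experiment",
    "run_method_table",
    "rank_methods",
]


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: dict  # subject_id -> fold index

    def subjects_in(self, fold: int) -> set:
        return {s for s, f in self.fold_of.items() if f == fold}


def assign_folds(recordings: list[TriaxialSeries], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deal shuffled subjects round-robin to k folds, stratified by class.

    Both recordings of a subject share its fold; fold sizes differ by at
    most one subject per class.
    """
    by_subject: dict[str, str] = {}
    for rec in recordings:
        prev = by_subject.setdefault(rec.subject_id, rec.label)
        if prev != rec.label:
            raise ValueError(f"subject {rec.subject_id} appears with two labels")
    if len(by_subject) < k:
        raise ValueError(f"need at least {k} subjects for {k} folds, have {len(by_subject)}")

    rng = substream(seed, "folds")
    fold_of: dict[str, int] = {}
    start = 0  # continue dealing across classes so totals differ by <= 1
    for label in ("PD", "HP"):
        subjects = sorted(s for s, lab in by_subject.items() if lab == label)
        rng.shuffle(subjects)
        for i, s in enumerate(subjects):
            fold_of[s] = (start + i) % k
        start = (start + len(subjects)) % k
    return FoldAssignment(k=k, fold_of=fold_of)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(predictions, labels) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with PD positive.

    TP: PD predicted PD; TN: HP predicted HP; FP: HP predicted PD;
    FN: PD predicted HP.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError(
            f"predictions ({predictions.shape}) and labels ({labels.shape}) length mismatch"
        )
    pos = POSITIVE_LABEL
    tp = int(np.sum((labels == pos) & (predictions == pos)))
    tn = int(np.sum((labels != pos) & (predictions != pos)))
    fp = int(np.sum((labels != pos) & (predictions == pos)))
    fn = int(np.sum((labels == pos) & (predictions != pos)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


@dataclass(frozen=True)
class FoldMetrics:
    counts: ConfusionCounts
    accuracy: float  # all four as percentages
    precision: float
    recall: float
    f1: float


def metrics(c: ConfusionCounts) -> FoldMetrics:
    """Accuracy, precision, recall, F1 (in %) from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated windows")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return FoldMetrics(
        counts=c, accuracy=100 * accuracy, precision=100 * precision,
        recall=100 * recall, f1=100 * f1,
    )


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold and mean metrics for one augmentation method."""

    method: str
    folds: tuple[FoldMetrics, ...]

    def _mean(self, attr: str) -> float:
        return float(np.mean([getattr(f, attr) for f in self.folds]))

    @property
    def accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def precision(self) -> float:
        return self._mean("precision")

    @property
    def recall(self) -> float:
        return self._mean("recall")

    @property
    def f1(self) -> float:
        return self._mean("f1")


def _window_arrays(windows: list[Window], stft: StftParams, fs: float):
    X = featurize(windows, stft, fs)
    y = np.array([0 if w.label == "PD" else 1 for w in windows])
    labels = np.array([w.label for w in windows])
    return X, y, labels


def run_experiment(
    cohort: list[TriaxialSeries],
    method: str | AugmentationSpec | None,
    *,
    filter_spec: FilterSpec = FilterSpec(),
    stft_params: StftParams = StftParams(),
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    k: int = 5,
    seed: int = 0,
    augmentation_factor: float = 1.0,
) -> MetricsReport:
    """One method's k-fold subject-independent CV run.

    method: a study-table label ("Nothing", "R", ..., "R&S&M"), an
    AugmentationSpec, or None for the no-augmentation baseline.
    Augmentation is applied to training windows only; test windows are
    never touched.
    """
    if isinstance(method, str):
        method_name = method
        spec_template = method_spec(method, factor=augmentation_factor)
    elif method is None:
        method_name, spec_template = "Nothing", None
    else:
        method_name, spec_template = "&".join(method.operators), method

    fs = cohort[0].sampling_rate
    windows_by_rec = {rec.recording_id: preprocess_recording(rec, filter_spec)
                      for rec in cohort}
    assignment = assign_folds(cohort, k=k, seed=seed)

    fold_results = []
    for fold in range(k):
        test_subjects = assignment.subjects_in(fold)
        train_windows: list[Window] = []
        test_windows: list[Window] = []
        for rec in cohort:
            target = test_windows if rec.subject_id in test_subjects else train_windows
            target.extend(windows_by_rec[rec.recording_id])

        train_subject_ids = {w.subject_id for w in train_windows}
        assert not (train_subject_ids & {w.subject_id for w in test_windows}), (
            f"subject leakage in fold {fold}"
        )

        if spec_template is not None:
            fold_spec = AugmentationSpec(
                operators=spec_template.operators,
                factor=spec_template.factor,
                rotation_range_deg=spec_template.rotation_range_deg,
                jitter_sigma=spec_template.jitter_sigma,
                scale_sigma=spec_template.scale_sigma,
                warp_sigma=spec_template.warp_sigma,
                warp_knots=spec_template.warp_knots,
                max_segments=spec_template.max_segments,
                seed=child_seed(seed, "augment", method_name, fold),
            )
            train_windows = expand_training_set(train_windows, fold_spec)

        X_train, y_train, _ = _window_arrays(train_windows, stft_params, fs)
        X_test, _, test_labels = _window_arrays(test_windows, stft_params, fs)

        fold_train_cfg = TrainConfig(
            epochs=train_config.epochs, batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            seed=child_seed(seed, "train", fold),
        )
        classifier = build_model(
            model_config, X_train.shape[1:], seed=child_seed(seed, "init", fold)
        )
        train(classifier, X_train, y_train, fold_train_cfg)
        _, predicted = predict(classifier, X_test)
        fold_results.append(metrics(confusion_counts(predicted, test_labels)))

    return MetricsReport(method=method_name, folds=tuple(fold_results))


def run_method_table(cohort, methods=None, **kwargs) -> list[MetricsReport]:
    """Run the full study method table (baseline + 11 augmentations)."""
    if methods is None:
        methods = list(METHOD_TABLE)
    return [run_experiment(cohort, m, **kwargs) for m in methods]


def rank_methods(reports: list[MetricsReport]) -> pd.DataFrame:
    """Rank methods by F1 (desc), ties by accuracy then method name.

    Adds delta-vs-baseline columns when a "Nothing" row is present.
    """
    if len(reports) < 2:
        raise ValueError("ranking needs at least two method reports")
    rows = [
        {"method": r.method, "accuracy": r.accuracy, "precision": r.precision,
         "recall": r.recall, "f1": r.f1}
        for r in reports
    ]
    df = pd.DataFrame(rows)
    baseline = df.loc[df["method"] == "Nothing"]
    if len(baseline) == 1:
        df["f1_vs_baseline"] = df["f1"] - float(baseline["f1"].iloc[0])
        df["accuracy_vs_baseline"] = df["accuracy"] - float(baseline["accuracy"].iloc[0])
    df = df.sort_values(
        by=["f1", "accuracy", "method"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.index = pd.RangeIndex(1, len(df) + 1, name="rank")
    return df
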