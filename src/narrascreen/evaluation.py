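"""Metrics for label-output classifiers and the repeated-resampling harness.

The classifiers here emit hard labels, not scores, so the ROC has a single
interior vertex and its AUC collapses to (sensitivity + specificity) / 2.
The full pipeline evaluation re-draws the majority down-sample and the
train/test split on every repeat (per-repeat seed = seed + repeat index),
retrains, and aggregates per-repeat metrics by their arithmetic mean.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classifier import (
    ClassifierSpec,
    classify_narrative,
    train_pair_classifier,
)
from .corpus import (
    NarrativeRecord,
    balance_downsample,
    check_unique_ids,
    filter_min_words,
    make_split,
)
from .errors import ValidationError
from .pairs import build_training_set, pairs_as_arrays

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table with class 1 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValidationError("confusion counts must be non-negative")
        if sum(counts) == 0:
            raise ValidationError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


def confusion_from_labels(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred length mismatch")
    tp = fp = tn = fn = 0
    for truth, pred in zip(y_true, y_pred):
        if truth not in (0, 1) or pred not in (0, 1):
            raise ValidationError("labels must be 0 or 1")
        if truth == 1:
            tp, fn = tp + (pred == 1), fn + (pred == 0)
        else:
            tn, fp = tn + (pred == 0), fp + (pred == 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, precision and positive-class F1.

    Metrics with a zero denominator come back as None (undefined), never
    coerced to 0.
    """
    sensitivity = _ratio(c.tp, c.tp + c.fn)
    specificity = _ratio(c.tn, c.tn + c.fp)
    precision = _ratio(c.tp, c.tp + c.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
    }


def auc_binary(c: ConfusionCounts) -> float | None:
    """AUC of the two-point ('stepped') ROC of a label-only classifier.

    Equals (sensitivity + specificity) / 2; None if either is undefined.
    """
    m = confusion_metrics(c)
    if m["sensitivity"] is None or m["specificity"] is None:
        return None
    return (m["sensitivity"] + m["specificity"]) / 2


def round_report(value: float | None, ndigits: int = 2) -> float | None:
    """Half-even rounding used for printed report values."""
    return None if value is None else round(value, ndigits)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for one full Model-#3 style pipeline run."""

    min_words: int = 30
    train_per_class: int | None = None  # default: round(17/19 * class size)
    set3_size: int | None = None  # default: |set1| + |set2|
    classifier: ClassifierSpec | None = None  # default spec, input_dim from data


@dataclass(frozen=True)
class RepeatResult:
    repeat_index: int
    seed: int
    counts: ConfusionCounts
    metrics: dict[str, float | None]
    auc: float | None
    stopped_epoch: int
    train_per_class: int
    n_test: int


@dataclass
class EvalReport:
    """Per-repeat and aggregate evaluation results."""

    repeats: list[RepeatResult]
    seeds: list[int]
    n_repeats: int
    mean_metrics: dict[str, float | None] = field(default_factory=dict)
    mean_auc: float | None = None
    pooled_counts: ConfusionCounts | None = None
    pooled_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "seeds": self.seeds,
            "mean_metrics": self.mean_metrics,
            "mean_auc": self.mean_auc,
            "pooled_counts": None
            if self.pooled_counts is None
            else vars(self.pooled_counts).copy(),
            "pooled_auc": self.pooled_auc,
            "rounded": {
                "auc": round_report(self.mean_auc),
                **{
                    name: round_report(self.mean_metrics.get(name))
                    for name in METRIC_NAMES
                },
            },
            "repeats": [
                {
                    "repeat_index": r.repeat_index,
                    "seed": r.seed,
                    "counts": {
                        "tp": r.counts.tp,
                        "fp": r.counts.fp,
                        "tn": r.counts.tn,
                        "fn": r.counts.fn,
                    },
                    "metrics": r.metrics,
                    "auc": r.auc,
                    "stopped_epoch": r.stopped_epoch,
                    "train_per_class": r.train_per_class,
                    "n_test": r.n_test,
                }
                for r in self.repeats
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv(self, path: str | Path, model_name: str = "model3") -> None:
        """One-row summary mirroring the comparison-table columns."""
        with Path(path).open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(
                ["Model", "AUC", "F1 score", "Sensitivity (Recall)",
                 "Specificity"]
            )
            writer.writerow(
                [
                    model_name,
                    round_report(self.mean_auc),
                    round_report(self.mean_metrics.get("f1")),
                    round_report(self.mean_metrics.get("sensitivity")),
                    round_report(self.mean_metrics.get("specificity")),
                ]
            )


def _mean_defined(values: Sequence[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def aggregate_report(repeats: Sequence[RepeatResult], seeds: Sequence[int]) -> EvalReport:
    mean_metrics = {
        name: _mean_defined([r.metrics[name] for r in repeats])
        for name in METRIC_NAMES
    }
    pooled = repeats[0].counts
    for r in repeats[1:]:
        pooled = pooled + r.counts
    return EvalReport(
        repeats=list(repeats),
        seeds=list(seeds),
        n_repeats=len(repeats),
        mean_metrics=mean_metrics,
        mean_auc=_mean_defined([r.auc for r in repeats]),
        pooled_counts=pooled,
        pooled_auc=auc_binary(pooled),
    )


def run_single_repeat(
    records: Sequence[NarrativeRecord],
    vectors: Mapping[str, np.ndarray],
    config: PipelineConfig,
    seed: int,
    repeat_index: int = 0,
) -> RepeatResult:
    """One pipeline pass: balance, split, augment, train, test."""
    balanced = balance_downsample(records, seed=seed)
    split = make_split(balanced, train_per_class=config.train_per_class,
                       seed=seed)

    pairs = build_training_set(split, vectors, seed=seed,
                               set3_size=config.set3_size)
    X, y = pairs_as_arrays(pairs)

    spec = config.classifier or ClassifierSpec(input_dim=X.shape[1])
    if spec.input_dim != X.shape[1]:
        raise ValidationError(
            f"classifier input_dim {spec.input_dim} does not match feature "
            f"dimension {X.shape[1]}"
        )
    spec = replace(spec, seed=seed)
    model = train_pair_classifier((X, y), spec)

    references = {
        cls_label: np.vstack([vectors[i] for i in split.train_ids[cls_label]])
        for cls_label in (0, 1)
    }
    label_by_id = {rec.subject_id: rec.label for rec in balanced}
    y_true, y_pred = [], []
    for subject_id in split.all_test_ids:
        pred = classify_narrative(model, vectors[subject_id], references)
        y_true.append(label_by_id[subject_id])
        y_pred.append(pred.label)

    counts = confusion_from_labels(y_true, y_pred)
    return RepeatResult(
        repeat_index=repeat_index,
        seed=seed,
        counts=counts,
        metrics=confusion_metrics(counts),
        auc=auc_binary(counts),
        stopped_epoch=model.stopped_epoch,
        train_per_class=split.train_per_class,
        n_test=len(y_true),
    )


def repeat_evaluation(
    records: Sequence[NarrativeRecord],
    vectors: Mapping[str, np.ndarray],
    config: PipelineConfig = PipelineConfig(),
    n_repeats: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Run the full pipeline ``n_repeats`` times with derived seeds.

    Each repeat re-draws the class-0 down-sample and the train/test split
    (repeat seed = seed + repeat_index), rebuilds the pair sets, retrains
    the network, and evaluates on its held-out test narratives.
    """
    check_unique_ids(records)
    filtered = filter_min_words(records, min_words=config.min_words)
    if not filtered:
        raise ValidationError("no records survive the minimum-word filter")
    for rec in filtered:
        if rec.subject_id not in vectors:
            raise ValidationError(
                f"no embedding vector for subject {rec.subject_id!r}"
            )

    repeats: list[RepeatResult] = []
    seeds: list[int] = []
    for repeat_index in range(n_repeats):
        repeat_seed = seed + repeat_index
        try:
            repeats.append(
                run_single_repeat(
                    filtered, vectors, config, seed=repeat_seed,
                    repeat_index=repeat_index,
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"repeat {repeat_index} failed: {exc}"
            ) from exc
        seeds.append(repeat_seed)
    return aggregate_report(repeats, seeds)
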