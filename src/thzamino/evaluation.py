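"""Confusion-matrix metrics and structured evaluation reports.

Accuracy is trace/total of the confusion matrix; the per-class score
Pr_i = n_ii / sum_j n_ij normalizes by the true-class row (a recall form,
reported under the name "precision" to match the field's usage for this
metric pair).  The algebraic identity
sum_i row_i * Pr_i / total = Acc holds whenever every row is populated.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion_matrix",
    "accuracy",
    "precision_per_class",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """Counts n_ij indexed (true i, predicted j)."""

    counts: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def write(self, path) -> None:
        names = self.class_names or [str(i) for i in range(self.counts.shape[0])]
        np.savetxt(
            path, self.counts, fmt="%d", header="\t".join(names), delimiter="\t"
        )


def confusion_matrix(true_labels, pred_labels, n_classes: int) -> ConfusionMatrix:
    true_labels = np.asarray(true_labels, dtype=int)
    pred_labels = np.asarray(pred_labels, dtype=int)
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label arrays must have equal length")
    if true_labels.size and (
        true_labels.min() < 0
        or true_labels.max() >= n_classes
        or pred_labels.min() < 0
        or pred_labels.max() >= n_classes
    ):
        raise ValueError("label out of range")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (true_labels, pred_labels), 1)
    return ConfusionMatrix(counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_per_class(cm: ConfusionMatrix) -> list[float]:
    """Pr_i = n_ii / row-sum i; rows with no items yield NaN (undefined)."""
    row_sums = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.diag(cm.counts) / row_sums
    return [float(p) if rs > 0 else float("nan") for p, rs in zip(pr, row_sums)]


@dataclass
class EvalReport:
    accuracy: float
    per_class: list[float]
    class_names: list[str]
    split_tag: str
    model_config: dict = field(default_factory=dict)
    throughput_fps: float | None = None  # informational only

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "per_class": {
                    name: (None if np.isnan(p) else p)
                    for name, p in zip(self.class_names, self.per_class)
                },
                "split": self.split_tag,
                "model_config": self.model_config,
                "throughput_fps": self.throughput_fps,
            },
            indent=2,
        )


def evaluate(model, dataset, measure_fps: bool = False) -> EvalReport:
    """Predict a labeled dataset and tally Acc and Pr_i."""
    n_classes = len(dataset.class_names)
    if model.config.n_classes != n_classes:
        raise ValueError(
            f"model has {model.config.n_classes} classes, dataset {n_classes}"
        )
    t0 = time.perf_counter()
    _, labels = model.predict(dataset.X)
    elapsed = time.perf_counter() - t0
    cm = confusion_matrix(dataset.y, labels, n_classes)
    cm.class_names = list(dataset.class_names)
    return EvalReport(
        accuracy=accuracy(cm),
        per_class=precision_per_class(cm),
        class_names=list(dataset.class_names),
        split_tag=dataset.split_tag,
        model_config={"use_eca": model.config.use_eca,
                      "input_channels": model.config.input_channels},
        throughput_fps=(len(dataset) / elapsed if measure_fps and elapsed > 0 else None),
    )
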