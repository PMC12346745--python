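"""Confusion matrices and classification metrics.

Accuracy is (TP + TN) / total, precision TP / (TP + FP), recall
TP / (TP + FN), computed per class from a rows-actual x columns-predicted
confusion matrix. Aggregation conventions are explicit: ``micro`` pools
TP/FP/FN over classes (for single-label multiclass this makes micro
precision = micro recall = micro F1 = accuracy, an algebraic identity);
``macro`` takes unweighted means of per-class values. The headline report
pairs micro precision/recall with a macro F1, plus full per-class values,
so the convention behind every number is visible. 0/0 is defined as 0 (with
a warning) to keep macro averages finite when a class is absent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = actual class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(actual, predicted, k: int) -> ConfusionMatrix:
    """Tally actual vs predicted class indices into a K x K matrix."""
    actual = np.asarray(actual, dtype=np.int64)
    predicted = np.asarray(predicted, dtype=np.int64)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValueError("actual and predicted must be equal-length vectors")
    if actual.size and (actual.min() < 0 or actual.max() >= k
                        or predicted.min() < 0 or predicted.max() >= k):
        raise ValueError(f"class indices must lie in 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (actual, predicted), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correct predictions: trace / total."""
    if cm.total == 0:
        raise ValueError("accuracy is undefined for an empty matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_recall(cm: ConfusionMatrix, c: int) -> tuple[float, float]:
    """Per-class (precision, recall); 0/0 -> 0 with a warning."""
    tp = cm.counts[c, c]
    fp = cm.counts[:, c].sum() - tp
    fn = cm.counts[c, :].sum() - tp
    if tp + fp == 0 or tp + fn == 0:
        warnings.warn(
            f"class {c}: empty denominator, precision/recall defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    precision = float(tp / (tp + fp)) if tp + fp else 0.0
    recall = float(tp / (tp + fn)) if tp + fn else 0.0
    return precision, recall


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r else 0.0


def aggregate_metrics(cm: ConfusionMatrix, averaging: str) -> tuple[float, float, float]:
    """(precision, recall, F1) under micro or macro averaging."""
    if averaging == "micro":
        tp = np.trace(cm.counts)
        fp = cm.counts.sum(axis=0) - np.diag(cm.counts)
        fn = cm.counts.sum(axis=1) - np.diag(cm.counts)
        denom_p = tp + fp.sum()
        denom_r = tp + fn.sum()
        p = float(tp / denom_p) if denom_p else 0.0
        r = float(tp / denom_r) if denom_r else 0.0
        return p, r, _f1(p, r)
    if averaging == "macro":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per = [precision_recall(cm, c) for c in range(cm.k)]
        ps = [p for p, _ in per]
        rs = [r for _, r in per]
        f1s = [_f1(p, r) for p, r in per]
        return float(np.mean(ps)), float(np.mean(rs)), float(np.mean(f1s))
    raise ValueError(f"unknown averaging {averaging!r}")


@dataclass
class EvalReport:
    """Full evaluation of one scenario/partition.

    ``precision`` and ``recall`` are micro-averaged (hence equal to
    accuracy for single-label tasks); ``f1`` is macro-averaged.
    """

    scenario: str
    partition: str
    class_names: tuple[str, ...]
    confusion: ConfusionMatrix
    accuracy: float
    precision_micro: float
    recall_micro: float
    f1_macro: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "partition": self.partition,
            "class_names": list(self.class_names),
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.accuracy,
            "precision_micro": self.precision_micro,
            "recall_micro": self.recall_micro,
            "f1_macro": self.f1_macro,
            "per_class": self.per_class,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            f"scenario: {self.scenario} [{self.partition}] "
            f"(n={self.confusion.total})",
            f"accuracy={self.accuracy:.4f}  "
            f"precision(micro)={self.precision_micro:.4f}  "
            f"recall(micro)={self.recall_micro:.4f}  "
            f"F1(macro)={self.f1_macro:.4f}",
        ]
        for name, d in self.per_class.items():
            lines.append(
                f"  {name:<12} precision={d['precision']:.4f} "
                f"recall={d['recall']:.4f} f1={d['f1']:.4f}"
            )
        return "\n".join(lines)


def evaluate(
    actual,
    predicted,
    class_names: tuple[str, ...],
    scenario: str = "",
    partition: str = "",
) -> EvalReport:
    """Build a complete EvalReport from actual/predicted index vectors."""
    k = len(class_names)
    cm = confusion_matrix(actual, predicted, k)
    p_mi, r_mi, _ = aggregate_metrics(cm, "micro")
    _, _, f1_ma = aggregate_metrics(cm, "macro")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_class = {}
        for c, name in enumerate(class_names):
            p, r = precision_recall(cm, c)
            per_class[name] = {"precision": p, "recall": r, "f1": _f1(p, r)}
    return EvalReport(
        scenario=scenario,
        partition=partition,
        class_names=tuple(class_names),
        confusion=cm,
        accuracy=accuracy(cm),
        precision_micro=p_mi,
        recall_micro=r_mi,
        f1_macro=f1_ma,
        per_class=per_class,
    )


def plot_confusion(cm: ConfusionMatrix, class_names, ax=None):
    """Heatmap rendering of a confusion matrix (counts annotated)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * cm.k, 1 + 0.6 * cm.k))
    ax.imshow(cm.counts, cmap="Blues")
    ax.set_xticks(range(cm.k), class_names, rotation=45, ha="right")
    ax.set_yticks(range(cm.k), class_names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    for i in range(cm.k):
        for j in range(cm.k):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center",
                    fontsize=8)
    return ax
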