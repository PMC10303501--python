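"""Confusion matrices, precision/recall/F1, and replicate summaries.

Conventions follow the agronomic-classification literature this pipeline
serves: confusion-matrix *rows* are the predicted class and *columns* the
true class (so column sums equal per-class test counts); per-class
precision P = TP/(TP+FP), recall R = TP/(TP+FN), F1 = 2PR/(P+R), with the
0/0 cases defined as 0 (with a warning); the macro average is the
unweighted mean over classes. Replicate accuracies are summarized as
mean +/- standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = predicted class, columns = true class."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise DataError(f"counts shape {self.counts.shape} != ({k}, {k})")
        if (self.counts < 0).any():
            raise DataError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0


def confusion(true_labels, predicted_labels, class_order: list[str]) -> ConfusionMatrix:
    """Count ``counts[p, t] = #{i : pred_i = p, true_i = t}``."""
    true_labels = [str(x) for x in true_labels]
    predicted_labels = [str(x) for x in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise DataError("true and predicted label vectors differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    unknown = (set(true_labels) | set(predicted_labels)) - set(index)
    if unknown:
        raise DataError(f"labels not in class_order: {sorted(unknown)}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


@dataclass
class MetricsReport:
    class_order: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    degenerate_classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "per_class": {c: {"precision": float(p), "recall": float(r), "f1": float(f)}
                          for c, p, r, f in zip(self.class_order, self.precision,
                                                self.recall, self.f1)},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "degenerate_classes": self.degenerate_classes,
        }


def precision_recall_f1(cm: ConfusionMatrix, average: str = "macro") -> MetricsReport:
    """Per-class and averaged P/R/F1 from a confusion matrix.

    A class never predicted (TP+FP = 0) or never present (TP+FN = 0) gets
    the 0/0 convention value 0 and is listed in ``degenerate_classes``.
    ``average="micro"`` additionally replaces the macro values with
    micro-averaged ones (equal to accuracy for single-label problems).
    """
    c = cm.counts
    tp = np.diag(c).astype(float)
    fp = c.sum(axis=1) - tp   # row sums: predicted-as-k
    fn = c.sum(axis=0) - tp   # column sums: truly-k
    degenerate = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1.0), 0.0)
    for k, cls in enumerate(cm.class_order):
        if tp[k] + fp[k] == 0 or tp[k] + fn[k] == 0:
            degenerate.append(cls)
    if degenerate:
        warnings.warn(f"0/0 metrics set to 0 for classes {degenerate}", stacklevel=2)
    if average == "micro":
        micro_p = micro_r = float(tp.sum() / c.sum()) if c.sum() else 0.0
        macro = (micro_p, micro_r, micro_p)
    else:
        macro = (float(precision.mean()), float(recall.mean()), float(f1.mean()))
    return MetricsReport(class_order=list(cm.class_order), precision=precision,
                         recall=recall, f1=f1, macro_precision=macro[0],
                         macro_recall=macro[1], macro_f1=macro[2],
                         accuracy=cm.accuracy, degenerate_classes=degenerate)


def replicate_summary(values, convention: str = "sample") -> tuple[float, float]:
    """Mean and spread over replicate runs, as ``(mean, se)``.

    Conventions for the +/- value:

    * ``"sample"`` (default): sample standard deviation (n-1) / sqrt(n) —
      the standard error of the mean;
    * ``"population"``: population standard deviation (n) / sqrt(n);
    * ``"population_sd"``: population standard deviation itself, not
      divided by sqrt(n) — this is the convention that reproduces the +/-
      values printed in some published replicate tables.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DataError("replicate summary needs at least 2 values")
    if convention == "sample":
        spread = values.std(ddof=1) / np.sqrt(values.size)
    elif convention == "population":
        spread = values.std(ddof=0) / np.sqrt(values.size)
    elif convention == "population_sd":
        spread = values.std(ddof=0)
    else:
        raise DataError(f"unknown SE convention {convention!r}")
    return float(values.mean()), float(spread)


def plot_confusion(cm: ConfusionMatrix, path, title: str = "") -> None:
    """Save a heatmap of the confusion matrix (rows predicted, cols true)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("true class")
    ax.set_ylabel("predicted class")
    ax.set_xticks(range(len(cm.class_order)), cm.class_order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(cm.class_order)), cm.class_order, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
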