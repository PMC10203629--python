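"""Confusion-matrix construction and classification metrics.

Conventions follow the study's reporting: the confusion matrix has true
classes on rows and predicted classes on columns; the row-normalized form
divides each row by its support so the diagonal holds per-class recall.
Per-class metrics are one-vs-rest counts

    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2*TP / (2*TP + FP + FN)
    accuracy  = (TP + TN) / (TP + TN + FP + FN)   (one-vs-rest variant)

with headline accuracy reported as trace/total and aggregate precision,
recall and F1 as unweighted (macro) class means.  A class with zero support
or zero predictions reports 0 for the undefined metric and is flagged with
a warning rather than emitting NaN.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K matching class_names")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\pred", *self.class_names])
            for name, row in zip(self.class_names, self.counts):
                writer.writerow([name, *row.tolist()])

    def to_heatmap(self, path: str | Path) -> None:
        """Optional row-normalized heatmap image (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(row_normalize(self), cmap="Blues", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.class_names)))
        ax.set_yticks(range(len(self.class_names)))
        ax.set_xticklabels(self.class_names, rotation=90, fontsize=6)
        ax.set_yticklabels(self.class_names, fontsize=6)
        ax.set_xlabel("Predicted label")
        ax.set_ylabel("True label")
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def confusion_matrix(
    true_labels, predicted_labels, num_classes: int, class_names=None
) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true == i and predicted == j}."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors differ in length")
    if len(t) and (t.min() < 0 or t.max() >= num_classes
                   or p.min() < 0 or p.max() >= num_classes):
        raise ValueError(f"labels must lie in [0, {num_classes})")
    counts = np.bincount(t * num_classes + p, minlength=num_classes * num_classes)
    names = list(class_names) if class_names else [str(i) for i in range(num_classes)]
    return ConfusionMatrix(counts.reshape(num_classes, num_classes), names)


def one_vs_rest_counts(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """Per-class TP/FP/FN/TN derived from the confusion matrix."""
    c = cm.counts
    tp = np.diag(c).astype(np.int64)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    tn = cm.total - tp - fp - fn
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros(len(num), dtype=float)
    ok = den > 0
    if not ok.all():
        warnings.warn(f"{what} undefined for {int((~ok).sum())} class(es); "
                      "reporting 0", stacklevel=3)
    out[ok] = num[ok] / den[ok]
    return out


def metrics(cm: ConfusionMatrix) -> dict:
    """Per-class and macro recall/precision/F1, overall and one-vs-rest
    accuracy, from the confusion matrix alone."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = one_vs_rest_counts(cm)
    tp, fp, fn, tn = counts["TP"], counts["FP"], counts["FN"], counts["TN"]
    recall = _safe_div(tp, tp + fn, "recall")
    precision = _safe_div(tp, tp + fp, "precision")
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "F1")
    ovr_accuracy = (tp + tn) / cm.total
    return {
        "class_names": list(cm.class_names),
        "support": (tp + fn).tolist(),
        "recall": recall.tolist(),
        "precision": precision.tolist(),
        "f1": f1.tolist(),
        "one_vs_rest_accuracy": ovr_accuracy.tolist(),
        "accuracy": float(np.trace(cm.counts) / cm.total),
        "macro_recall": float(recall.mean()),
        "macro_precision": float(precision.mean()),
        "macro_f1": float(f1.mean()),
    }


def row_normalize(cm: ConfusionMatrix) -> np.ndarray:
    """Each row divided by its support (diagonal = per-class recall);
    zero-support rows are emitted as zeros with a warning."""
    support = cm.counts.sum(axis=1, keepdims=True)
    if (support == 0).any():
        warnings.warn("zero-support class row(s) emitted as zeros", stacklevel=2)
    out = np.zeros(cm.counts.shape, dtype=float)
    ok = support[:, 0] > 0
    out[ok] = cm.counts[ok] / support[ok]
    return out
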