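"""Confusion-matrix accumulation and segmentation evaluation metrics.

All metrics derive from a K x K pixel-count confusion matrix (rows: true
class, columns: predicted class) aggregated over the evaluation set.  Per
class (one-vs-rest): precision TP/(TP+FP), recall TP/(TP+FN), F1 (their
harmonic mean) and IoU TP/(TP+FN+FP).  Globally: overall accuracy
trace/total, mIoU (the unweighted class mean of IoU) and FWIoU (IoU weighted
by each class's ground-truth pixel frequency and summed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CLASS_NAMES, IGNORE_LABEL, N_CLASSES


@dataclass
class ConfusionMatrix:
    n_classes: int = N_CLASSES
    counts: np.ndarray = None

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((self.n_classes, self.n_classes), dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (self.n_classes, self.n_classes):
                raise ValueError("counts must be K x K")
            if (self.counts < 0).any():
                raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accumulate(self, pred_labels, true_labels, ignore: int = IGNORE_LABEL):
        """Add per-pixel counts; ignore-labelled truth pixels are skipped."""
        pred = np.asarray(pred_labels).ravel()
        true = np.asarray(true_labels).ravel()
        if pred.shape != true.shape:
            raise ValueError("pred and true shapes differ")
        keep = true != ignore
        pred, true = pred[keep], true[keep]
        k = self.n_classes
        if pred.size and (pred.min() < 0 or pred.max() >= k
                          or true.min() < 0 or true.max() >= k):
            raise ValueError(f"labels outside 0..{k - 1}")
        self.counts += np.bincount(
            true * k + pred, minlength=k * k
        ).reshape(k, k)
        return self

    def one_vs_rest(self, c: int):
        """(TP, FP, FN, TN) for class c."""
        tp = int(self.counts[c, c])
        fp = int(self.counts[:, c].sum() - tp)
        fn = int(self.counts[c, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass
class MetricsReport:
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    iou: np.ndarray
    accuracy: float
    miou: float
    fwiou: float
    undefined: np.ndarray = field(default=None)
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))

    def to_frame(self) -> pd.DataFrame:
        """Per-class table shaped like the usual results listing."""
        names = [self.class_names.get(i, str(i)) for i in range(len(self.iou))]
        return pd.DataFrame(
            {"Precision": self.precision, "Recall": self.recall,
             "F1": self.f1, "IoU": self.iou},
            index=pd.Index(names, name="Category"),
        )

    def to_dict(self) -> dict:
        return {
            "per_class": {
                self.class_names.get(i, str(i)): {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "iou": float(self.iou[i]),
                }
                for i in range(len(self.iou))
            },
            "accuracy": float(self.accuracy),
            "miou": float(self.miou),
            "fwiou": float(self.fwiou),
        }


def _safe_div(num, den):
    """num/den with 0/0 -> 0 plus an `undefined` flag."""
    und = den == 0
    out = np.where(und, 0.0, num / np.where(und, 1, den))
    return out, und


def compute_report(cm: ConfusionMatrix) -> MetricsReport:
    """Derive all metrics from an accumulated confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.n_classes
    tp = np.diag(cm.counts).astype(np.float64)
    col = cm.counts.sum(axis=0).astype(np.float64)     # predicted per class
    row = cm.counts.sum(axis=1).astype(np.float64)     # true per class
    precision, u1 = _safe_div(tp, col)
    recall, u2 = _safe_div(tp, row)
    f1, u3 = _safe_div(2 * precision * recall, precision + recall)
    iou, u4 = _safe_div(tp, row + col - tp)
    accuracy = float(tp.sum() / cm.total)
    miou = float(iou.mean())
    freq = row / cm.total
    fwiou = float((freq * iou).sum())
    return MetricsReport(precision, recall, f1, iou, accuracy, miou, fwiou,
                         undefined=u1 | u2 | u3 | u4)


def evaluate_labels(pred_labels, true_labels, n_classes: int = N_CLASSES,
                    ignore: int = IGNORE_LABEL) -> MetricsReport:
    """One-shot evaluation of a predicted label raster against truth."""
    cm = ConfusionMatrix(n_classes)
    cm.accumulate(pred_labels, true_labels, ignore=ignore)
    return compute_report(cm)
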