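"""Confusion matrices and accuracy / precision / recall / F1.

Multiclass metrics are computed one-vs-rest per class from the
confusion matrix and macro-averaged (unweighted class mean).  Any
precision/recall/F1 whose denominator is zero is defined as 0 so that
reports stay total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, DataError

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics"]


@dataclass
class ConfusionMatrix:
    """Counts indexed (true class, predicted class)."""

    counts: np.ndarray
    class_order: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order,
                            columns=self.class_order)


@dataclass
class MetricsReport:
    per_class: pd.DataFrame  # rows = classes; tp/tn/fp/fn/precision/recall/f1
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.to_dict(orient="index"),
        }


def confusion(y_true, y_pred, class_order) -> ConfusionMatrix:
    """Count (true, predicted) pairs; absent classes keep zero rows/cols."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ContractError("y_true and y_pred lengths differ")
    co = list(class_order)
    idx = {c: i for i, c in enumerate(co)}
    counts = np.zeros((len(co), len(co)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in idx or p not in idx:
            raise DataError(f"label {t if t not in idx else p!r} not in class_order")
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=co)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest per-class metrics plus overall accuracy and macro means."""
    total = cm.total
    if total == 0:
        raise ContractError("empty confusion matrix")
    c = cm.counts
    rows = []
    for i, cls in enumerate(cm.class_order):
        tp = int(c[i, i])
        fn = int(c[i, :].sum() - tp)
        fp = int(c[:, i].sum() - tp)
        tn = total - tp - fn - fp
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        f1 = _safe_div(2 * recall * precision, recall + precision)
        rows.append({
            "class": cls, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1,
        })
    per_class = pd.DataFrame(rows).set_index("class")
    return MetricsReport(
        per_class=per_class,
        accuracy=float(np.trace(c)) / total,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
    )
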