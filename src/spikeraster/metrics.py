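"""Confusion-matrix evaluation: per-class precision/recall/F1 and accuracy.

Per-class metrics are one-vs-rest on the percent scale:

    precision = TP/(TP+FP) * 100
    recall    = TP/(TP+FN) * 100
    F1        = 2*precision*recall/(precision+recall)

Overall accuracy is trace/total * 100, which for two classes reduces to
(TP+TN)/(TP+FP+TN+FN) and in general equals micro-averaged recall.
Values are kept at full precision; rounding (half-up, two decimals)
happens only when a report is rendered.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "precision_recall_f1",
    "accuracy",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """counts[i, j] = windows with true class i predicted as class j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k classes")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_id: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against the rest."""
        i = self.classes.index(class_id)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Tally a k x k confusion matrix (rows true, columns predicted)."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = tuple(sorted(set(y_true) | set(y_pred)))
    else:
        classes = tuple(classes)
        known = set(classes)
        for lbl in y_true + y_pred:
            if lbl not in known:
                raise ValueError(f"unknown label {lbl!r}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def precision_recall_f1(cm: ConfusionMatrix, class_id: str) -> tuple[float, float, float]:
    """One-vs-rest (precision %, recall %, F1 %); NaN where undefined."""
    tp, fp, fn, _ = cm.one_vs_rest(class_id)
    if tp + fp == 0:
        warnings.warn(f"precision undefined for class {class_id!r} (no predictions)")
        precision = float("nan")
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn(f"recall undefined for class {class_id!r} (no true windows)")
        recall = float("nan")
    else:
        recall = 100.0 * tp / (tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f1


def f1_from_percent(precision: float, recall: float) -> float:
    """F1 on the percent scale from percent precision/recall."""
    return 2.0 * precision * recall / (precision + recall)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def _round2(x: float) -> float:
    if np.isnan(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 plus overall accuracy, in percent."""

    cm: ConfusionMatrix
    per_class: dict[str, tuple[float, float, float]]
    overall_accuracy: float

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = []
        rnd = _round2 if rounded else (lambda v: v)
        for cls, (p, r, f1) in self.per_class.items():
            rows.append({"class": cls, "precision": rnd(p),
                         "recall": rnd(r), "f1": rnd(f1)})
        frame = pd.DataFrame(rows)
        frame["accuracy"] = rnd(self.overall_accuracy)
        return frame

    def to_json(self, path: str | Path | None = None, rounded: bool = True) -> str:
        rnd = _round2 if rounded else (lambda v: v)
        doc = {
            "classes": list(self.cm.classes),
            "confusion": self.cm.counts.tolist(),
            "per_class": {
                c: {"precision": rnd(p), "recall": rnd(r), "f1": rnd(f)}
                for c, (p, r, f) in self.per_class.items()
            },
            "accuracy": rnd(self.overall_accuracy),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(y_true, y_pred, classes=None) -> MetricsReport:
    """Full report from label sequences."""
    cm = confusion(y_true, y_pred, classes=classes)
    per_class = {c: precision_recall_f1(cm, c) for c in cm.classes}
    return MetricsReport(cm=cm, per_class=per_class, overall_accuracy=accuracy(cm))
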