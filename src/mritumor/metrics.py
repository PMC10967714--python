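"""Classification and segmentation evaluation: confusion matrix, per-class
precision/recall/F1 (in percent, matching the field's reporting style),
one-vs-rest accuracies, and the Dice overlap coefficient for masks."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConfusionMatrix", "ClassReport", "confusion", "report", "dice"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # C x C, rows = true, cols = predicted
    classes: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassReport:
    """Per-class and aggregate classification metrics, in percent."""

    classes: list
    accuracy: float
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    ovr_accuracy: dict = field(default_factory=dict)  # one-vs-rest accuracy
    support: dict = field(default_factory=dict)
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0

    def as_dict(self, decimals: int = 2) -> dict:
        r = lambda v: round(float(v), decimals)
        return {
            "accuracy": r(self.accuracy),
            "macro_precision": r(self.macro_precision),
            "macro_recall": r(self.macro_recall),
            "macro_f1": r(self.macro_f1),
            "per_class": {
                str(c): {
                    "precision": r(self.precision[c]),
                    "recall": r(self.recall[c]),
                    "f1": r(self.f1[c]),
                    "ovr_accuracy": r(self.ovr_accuracy[c]),
                    "support": int(self.support[c]),
                }
                for c in self.classes
            },
        }


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Tally counts[i, j] = #(true = class_i, predicted = class_j)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    for lab in np.concatenate([y_true, y_pred]):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in the class list")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def _safe_ratio(num: float, den: float, zero_division: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (0/0); using zero_division value")
        return zero_division
    return num / den


def report(cm: ConfusionMatrix, zero_division: float = 0.0) -> ClassReport:
    """Accuracy, per-class precision/recall/F1 and macro averages (percent)."""
    M = cm.counts
    total = M.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = 100.0 * np.trace(M) / total
    rep = ClassReport(classes=cm.classes, accuracy=float(acc))
    for i, c in enumerate(cm.classes):
        tp = M[i, i]
        fp = M[:, i].sum() - tp
        fn = M[i, :].sum() - tp
        tn = total - tp - fp - fn
        p = _safe_ratio(tp, tp + fp, zero_division, f"precision[{c}]")
        r = _safe_ratio(tp, tp + fn, zero_division, f"recall[{c}]")
        f = _safe_ratio(2 * p * r, p + r, zero_division, f"f1[{c}]")
        rep.precision[c] = 100.0 * p
        rep.recall[c] = 100.0 * r
        rep.f1[c] = 100.0 * f
        rep.ovr_accuracy[c] = 100.0 * (tp + tn) / total
        rep.support[c] = int(M[i, :].sum())
    C = len(cm.classes)
    rep.macro_precision = sum(rep.precision.values()) / C
    rep.macro_recall = sum(rep.recall.values()) / C
    rep.macro_f1 = sum(rep.f1.values()) / C
    return rep


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks give 1.0."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must have the same shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)
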