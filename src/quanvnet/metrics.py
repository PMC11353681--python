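"""Confusion-matrix classification report for the binary task.

Per-class precision, recall, F1 and support, overall accuracy, macro and
support-weighted averages, and one-vs-rest TPR/FPR.  In the binary case
the support-weighted average of recall equals accuracy exactly — the
report asserts nothing, but the test suite checks the identity.

Conventions: precision_k = TP_k / predicted_k (0 with a warning flag
when nothing is predicted as k); TPR_k = recall_k; FPR_k is one-vs-rest,
FP_k / (n − support_k), i.e. the fraction of non-k items predicted k.
Published tables occasionally print other FPR conventions; this module
sticks to one-vs-rest.  Values are kept at full precision and rounded
only for display (2 decimals, half away from zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion",
    "report",
    "reconstruct_confusion",
]


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows = true class (0, 1), columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2):
            raise ValueError("confusion matrix must be 2x2")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        self.counts = c

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassificationReport:
    precision: np.ndarray  # per class (0, 1)
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    tpr: np.ndarray
    fpr: np.ndarray
    zero_division_flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class": {
                str(k): {
                    "precision": float(self.precision[k]),
                    "recall": float(self.recall[k]),
                    "f1": float(self.f1[k]),
                    "support": int(self.support[k]),
                    "tpr": float(self.tpr[k]),
                    "fpr": float(self.fpr[k]),
                }
                for k in (0, 1)
            },
            "accuracy": float(self.accuracy),
            "macro_avg": {"precision": float(self.macro_precision),
                          "recall": float(self.macro_recall),
                          "f1": float(self.macro_f1)},
            "weighted_avg": {"precision": float(self.weighted_precision),
                             "recall": float(self.weighted_recall),
                             "f1": float(self.weighted_f1)},
            "n": int(self.support.sum()),
            "zero_division_flags": list(self.zero_division_flags),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Aligned table: per-class rows, accuracy, averages, TPR/FPR."""
        n = int(self.support.sum())

        def f(x):
            return f"{round2(x):.2f}"

        rows = [
            f"{'':>14}{'precision':>11}{'recall':>9}{'f1-score':>10}{'support':>9}",
            "",
        ]
        for k in (0, 1):
            rows.append(f"{k:>14}{f(self.precision[k]):>11}{f(self.recall[k]):>9}"
                        f"{f(self.f1[k]):>10}{int(self.support[k]):>9}")
        rows.append("")
        rows.append(f"{'accuracy':>14}{'':>11}{'':>9}{f(self.accuracy):>10}{n:>9}")
        rows.append(f"{'macro avg':>14}{f(self.macro_precision):>11}"
                    f"{f(self.macro_recall):>9}{f(self.macro_f1):>10}{n:>9}")
        rows.append(f"{'weighted avg':>14}{f(self.weighted_precision):>11}"
                    f"{f(self.weighted_recall):>9}{f(self.weighted_f1):>10}{n:>9}")
        rows.append("")
        rows.append(f"{'TPR':>14}{f(self.tpr[0]):>11}{f(self.tpr[1]):>9}")
        rows.append(f"{'FPR':>14}{f(self.fpr[0]):>11}{f(self.fpr[1]):>9}")
        return "\n".join(rows) + "\n"


def round2(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """counts[i][j] = number of samples with true class i predicted j."""
    t = np.asarray(y_true, dtype=int).ravel()
    p = np.asarray(y_pred, dtype=int).ravel()
    if t.size != p.size:
        raise ValueError("y_true and y_pred lengths differ")
    for v in (t, p):
        if v.size and not set(np.unique(v)) <= {0, 1}:
            raise ValueError("values must be binary")
    counts = np.zeros((2, 2), dtype=int)
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = int(np.sum((t == i) & (p == j)))
    return ConfusionMatrix(counts)


def report(cm: ConfusionMatrix) -> ClassificationReport:
    c = cm.counts
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    support = c.sum(axis=1)
    predicted = c.sum(axis=0)
    tp = np.diag(c).astype(float)
    flags = []
    precision = np.zeros(2)
    recall = np.zeros(2)
    for k in (0, 1):
        if predicted[k] > 0:
            precision[k] = tp[k] / predicted[k]
        else:
            flags.append(f"precision_{k}")
        if support[k] > 0:
            recall[k] = tp[k] / support[k]
        else:
            flags.append(f"recall_{k}")
    f1 = np.zeros(2)
    for k in (0, 1):
        denom = precision[k] + recall[k]
        f1[k] = 2 * precision[k] * recall[k] / denom if denom > 0 else 0.0
    accuracy = float(tp.sum() / n)
    weights = support / n
    fp = predicted - tp
    fpr = np.zeros(2)
    for k in (0, 1):
        rest = n - support[k]
        if rest > 0:
            fpr[k] = fp[k] / rest
        else:
            flags.append(f"fpr_{k}")
    return ClassificationReport(
        precision=precision, recall=recall, f1=f1, support=support,
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        weighted_precision=float(np.dot(weights, precision)),
        weighted_recall=float(np.dot(weights, recall)),
        weighted_f1=float(np.dot(weights, f1)),
        tpr=recall.copy(), fpr=fpr, zero_division_flags=flags,
    )


def reconstruct_confusion(recalls, supports) -> ConfusionMatrix:
    """Rebuild the 2x2 matrix from per-class recalls and supports.

    TP_k = round(recall_k * support_k); the off-diagonal of row k is the
    remainder.  Lets a printed report (recall + support columns) be
    round-tripped back into counts.
    """
    recalls = np.asarray(recalls, dtype=float)
    supports = np.asarray(supports, dtype=int)
    if recalls.shape != (2,) or supports.shape != (2,):
        raise ValueError("binary task: need exactly two recalls and supports")
    tp = np.round(recalls * supports).astype(int)
    if (tp < 0).any() or (tp > supports).any():
        raise ValueError("infeasible recall/support combination")
    counts = np.array([[tp[0], supports[0] - tp[0]],
                       [supports[1] - tp[1], tp[1]]])
    return ConfusionMatrix(counts)
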