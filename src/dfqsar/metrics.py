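"""Confusion-matrix metrics for imbalanced binary classification.

Five metrics are used throughout: accuracy, sensitivity (true-positive rate),
specificity (true-negative rate), Matthews correlation coefficient and
balanced accuracy = (sensitivity + specificity) / 2.  The positive class is
"binder"/"active".  Any metric with a zero denominator is reported as
undefined (``None``); an MCC whose denominator contains a zero factor is
reported as 0 with an explicit flag — the convention under which a classifier
that never predicts one class has zero correlation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "compute_metrics", "percent"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricsReport:
    """The five performance metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    mcc: float | None
    mcc_undefined_denominator: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_text(self) -> str:
        rows = [
            ("accuracy", self.accuracy),
            ("sensitivity", self.sensitivity),
            ("specificity", self.specificity),
            ("balanced accuracy", self.balanced_accuracy),
            ("MCC", self.mcc),
        ]
        width = max(len(k) for k, _ in rows)
        lines = []
        for k, v in rows:
            text = "undefined" if v is None else f"{v:.4f}"
            lines.append(f"{k:<{width}}  {text}")
        return "\n".join(lines)


def confusion(actual: Sequence[int], predicted: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN; labels are 1 (binder/active) and 0 (non-binder/inactive)."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape:
        raise ValueError(f"length mismatch: {a.shape} actual vs {p.shape} predicted")
    if a.size == 0:
        raise ValueError("empty label vectors")
    return ConfusionMatrix(
        tp=int(((a == 1) & (p == 1)).sum()),
        tn=int(((a == 0) & (p == 0)).sum()),
        fp=int(((a == 0) & (p == 1)).sum()),
        fn=int(((a == 1) & (p == 0)).sum()),
    )


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the five metrics from a confusion matrix.

    accuracy = (TP+TN)/n; sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    balanced accuracy = (sensitivity + specificity) / 2.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    if sensitivity is not None and specificity is not None:
        balanced = (sensitivity + specificity) / 2
    else:
        balanced = None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_flag = denom == 0
    if mcc_flag:
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(accuracy, sensitivity, specificity, balanced, mcc, mcc_flag)


def percent(fraction: float, ndigits: int = 1) -> float:
    """Express a fraction as a percentage rounded half-up to ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))
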