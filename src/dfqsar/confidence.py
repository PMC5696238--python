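"""Prediction-confidence binning.

Confidence = |P - 0.5| / 0.5 maps the consensus binder probability onto
[0, 1]: 0 at a coin-flip consensus, 1 at unanimity.  Out-of-fold predictions
are placed into ten equal-width confidence bins (left-closed, right-open,
final bin closed at 1) and the performance metrics are recomputed per bin.
In a well-behaved model accuracy rises with confidence, which makes the
statistic usable as an applicability guide when the model is deployed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .forest import prediction_confidence
from .metrics import MetricsReport, compute_metrics, confusion

__all__ = ["ConfidenceBin", "ConfidenceBinReport", "bin_predictions", "prediction_confidence"]


@dataclass
class ConfidenceBin:
    low: float
    high: float
    n: int
    metrics: MetricsReport | None  # None for an empty bin


@dataclass
class ConfidenceBinReport:
    bins: list[ConfidenceBin]

    @property
    def total(self) -> int:
        return sum(b.n for b in self.bins)

    def accuracies(self) -> list[float | None]:
        return [b.metrics.accuracy if b.metrics is not None else None for b in self.bins]

    def spearman_confidence_accuracy(self) -> float:
        """Rank correlation between bin index and bin accuracy over non-empty bins."""
        pairs = [(i, a) for i, a in enumerate(self.accuracies()) if a is not None]
        idx, acc = zip(*pairs)
        return float(spearmanr(idx, acc).statistic)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            m = b.metrics
            rows.append({
                "bin_low": b.low, "bin_high": b.high, "n": b.n,
                "accuracy": None if m is None else m.accuracy,
                "sensitivity": None if m is None else m.sensitivity,
                "specificity": None if m is None else m.specificity,
            })
        return pd.DataFrame(rows)


def bin_predictions(
    probabilities: np.ndarray, actual: np.ndarray, n_bins: int = 10
) -> ConfidenceBinReport:
    """Bin predictions by confidence and score each bin.

    Bins are equal-width over confidence in [0, 1], left-closed right-open,
    with the final bin closed so confidence 1.0 is counted.  Empty bins are
    reported with n = 0 and no metrics.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(actual, dtype=int)
    if p.size == 0:
        raise ValueError("no predictions to bin")
    if p.shape != y.shape:
        raise ValueError("probabilities and actual labels differ in length")
    conf = np.abs(p - 0.5) / 0.5
    which = np.clip(np.floor(conf * n_bins).astype(int), 0, n_bins - 1)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = []
    for b in range(n_bins):
        rows = which == b
        n = int(rows.sum())
        if n == 0:
            metrics = None
        else:
            metrics = compute_metrics(confusion(y[rows], (p[rows] >= 0.5).astype(int)))
        bins.append(ConfidenceBin(float(edges[b]), float(edges[b + 1]), n, metrics))
    return ConfidenceBinReport(bins)
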