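"""Applying a trained model to external assay data, and label-set concordance.

Two distinct questions arise when a binding-affinity model meets
high-throughput screening data.  First, how well do the *experimental* label
sets agree: treating one assay's binder/active calls as a prediction of the
other's gives a concordance confusion matrix (the 21 compounds shared by the
binding database and the ToxCast dimerization assays are the canonical
example).  Second, how well does the *model* extrapolate: predictions on the
full application set are scored against the assay outcomes, overall and
stratified by prediction confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .data_model import AssayRecord, DescriptorTable
from .forest import ForestModel, Prediction, predict_table
from .metrics import ConfusionMatrix, MetricsReport, compute_metrics, confusion

__all__ = ["ApplicationResult", "apply_model", "compare_label_sets"]

log = logging.getLogger(__name__)


@dataclass
class ApplicationResult:
    predictions: list[Prediction]
    matrix: ConfusionMatrix
    overall: MetricsReport
    high_confidence: MetricsReport | None
    low_confidence: MetricsReport | None
    high_confidence_matrix: ConfusionMatrix | None
    low_confidence_matrix: ConfusionMatrix | None
    confidence_cut: float
    n_not_determined: int

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"compound_id": p.compound_id, "probability": p.probability,
              "label": p.label, "confidence": p.confidence} for p in self.predictions]
        )


def apply_model(
    model: ForestModel,
    table: DescriptorTable,
    assay: Sequence[AssayRecord],
    confidence_cut: float = 0.5,
) -> ApplicationResult:
    """Predict every determined-outcome assay compound and score against the assay.

    Actives are the positive class.  Compounds with outcome ``not_determined``
    are excluded from the matrix (their count is logged).  Metrics are
    reported overall and split at ``confidence_cut`` into high- and
    low-confidence strata.
    """
    ids_in_table = set(table.compound_ids)
    unknown = [r.compound_id for r in assay if r.compound_id not in ids_in_table]
    if unknown:
        raise KeyError(f"assay compound(s) absent from descriptor table: {unknown}")
    determined = [r for r in assay if r.outcome != "not_determined"]
    n_nd = len(assay) - len(determined)
    if n_nd:
        log.info("%d assay compounds with undetermined outcome excluded", n_nd)
    if not determined:
        raise ValueError("no assay compounds with a determined outcome")
    sub = table.select_compounds([r.compound_id for r in determined])
    predictions = predict_table(model, sub)
    actual = [1 if r.outcome == "active" else 0 for r in determined]
    predicted = [1 if p.probability >= 0.5 else 0 for p in predictions]
    conf = [p.confidence for p in predictions]
    matrix = confusion(actual, predicted)
    overall = compute_metrics(matrix)

    def stratum(select: list[bool]) -> tuple[ConfusionMatrix | None, MetricsReport | None]:
        if not any(select):
            return None, None
        cm = confusion([a for a, s in zip(actual, select) if s],
                       [p for p, s in zip(predicted, select) if s])
        return cm, compute_metrics(cm)

    hi_cm, hi = stratum([c >= confidence_cut for c in conf])
    lo_cm, lo = stratum([c < confidence_cut for c in conf])
    return ApplicationResult(predictions, matrix, overall, hi, lo, hi_cm, lo_cm,
                             confidence_cut, n_nd)


def compare_label_sets(
    set_a: Sequence[int], set_b: Sequence[int]
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Concordance of two binary labelings of the same compounds.

    ``set_a`` is treated as a prediction of ``set_b`` (1 = binder/active).
    The agreement fraction is the resulting accuracy.  With one class absent
    from ``set_b`` — as when every shared compound is a database binder —
    specificity and balanced accuracy are undefined and flagged as such.
    """
    if len(set_a) != len(set_b):
        raise ValueError("label sets cover different compound counts")
    cm = confusion(actual=set_b, predicted=set_a)
    return cm, compute_metrics(cm)
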