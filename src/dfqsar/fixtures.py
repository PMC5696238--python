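"""Packaged copies of the study's printed summary tables.

Two concordance tables (the 21 compounds shared between the binding database
and the two ToxCast ERbeta dimerization assays; compound identities are
synthetic placeholders, the 2x2 structure is what is used) and the two
application-set prediction-vs-assay confusion matrices.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .metrics import ConfusionMatrix

__all__ = ["concordance_table", "application_matrix", "fixture_path"]

_CONCORDANCE = {"0480": "table1_concordance_0480.csv",
                "1440": "table2_concordance_1440.csv"}
_APPLICATION = {"0480": "table3_application_0480.json",
                "1440": "table4_application_1440.json"}


def fixture_path(name: str):
    return resources.files("dfqsar") / "data" / name


def concordance_table(assay: str) -> pd.DataFrame:
    """Per-compound EADB-label / ToxCast-outcome pairs for assay "0480" or "1440"."""
    return pd.read_csv(fixture_path(_CONCORDANCE[assay]))


def application_matrix(assay: str) -> ConfusionMatrix:
    """Model-prediction vs assay-outcome confusion matrix for assay "0480" or "1440"."""
    with fixture_path(_APPLICATION[assay]).open() as fh:
        d = json.load(fh)
    return ConfusionMatrix(tp=d["tp"], tn=d["tn"], fp=d["fp"], fn=d["fn"])
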