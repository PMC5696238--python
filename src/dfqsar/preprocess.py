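"""Low-information descriptor filtering.

Descriptors whose single most frequent value dominates the training set carry
almost no splitting information for a tree learner and are removed before
training (in the original study this step reduced 777 Mold2 descriptors to
447).  The filter is fit on the training table only; the surviving column
list is then applied verbatim to application tables to avoid leakage and
column mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .data_model import DescriptorTable

__all__ = ["FilterReport", "filter_low_information", "apply_filter"]


@dataclass
class FilterReport:
    """Which descriptors a dominance filter removed and kept, and at what cutoff."""

    removed_names: list[str]
    kept_names: list[str]
    dominance_threshold: float

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FilterReport":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(d["removed_names"], d["kept_names"], d["dominance_threshold"])


def _dominance(column: np.ndarray) -> float:
    """Fraction of rows holding the column's single most frequent value.

    Exact float equality defines "the same value": descriptor generators emit
    discretised/typed values, so no epsilon-bucketing is applied.
    """
    _, counts = np.unique(column, return_counts=True)
    return counts.max() / column.size


def filter_low_information(
    table: DescriptorTable, dominance_threshold: float = 0.95
) -> tuple[DescriptorTable, FilterReport]:
    """Drop descriptors whose most frequent value occurs in > threshold of compounds.

    Constant columns are removed at any admissible threshold.  Survivor column
    order is preserved.  Removing every descriptor is a hard error (the table
    would be untrainable).
    """
    if table.n_compounds == 0:
        raise ValueError("empty descriptor table")
    if not 0.5 < dominance_threshold <= 1.0:
        raise ValueError(f"dominance_threshold must be in (0.5, 1], got {dominance_threshold}")
    kept, removed = [], []
    for j, name in enumerate(table.descriptor_names):
        dom = _dominance(table.values[:, j])
        # constant columns carry no information and go at any threshold
        if dom == 1.0 or dom > dominance_threshold:
            removed.append(name)
        else:
            kept.append(name)
    if not kept:
        raise ValueError("all descriptors removed by dominance filter; table untrainable")
    return table.select_descriptors(kept), FilterReport(removed, kept, dominance_threshold)


def apply_filter(table: DescriptorTable, report: FilterReport) -> DescriptorTable:
    """Project an application table onto a previously fitted kept-column list."""
    return table.select_descriptors(report.kept_names)
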