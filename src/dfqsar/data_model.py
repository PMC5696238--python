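"""Domain types and readers for descriptor tables, binding-affinity records and assay outcomes.

The training endpoint is binary: a compound is an estrogen-receptor-beta
*binder* if its logRBA (log10 relative binding affinity) is at or above a
threshold, -5 by convention, otherwise a *non-binder*.  Compounds with several
logRBA measurements are labelled by strict majority vote of the per-value
labels; an exact tie is ambiguous and the compound is excluded from training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BINDER",
    "NON_BINDER",
    "EXCLUDED",
    "LOGRBA_THRESHOLD",
    "DescriptorTable",
    "ActivityRecord",
    "AssayRecord",
    "LabeledDataset",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_activity_records",
    "read_assay_records",
    "label_compound",
    "assemble_dataset",
]

log = logging.getLogger(__name__)

BINDER = "binder"
NON_BINDER = "non_binder"
EXCLUDED = "excluded"

#: Default logRBA cut-off: binder iff logRBA >= -5 (boundary inclusive).
LOGRBA_THRESHOLD = -5.0

ASSAY_OUTCOMES = frozenset({"active", "inactive", "not_determined"})


@dataclass
class DescriptorTable:
    """A compounds x descriptors numeric feature matrix.

    ``values[i, j]`` is the value of descriptor ``descriptor_names[j]`` for
    compound ``compound_ids[i]``.  IDs and names are unique; every cell is a
    finite float — missing values are rejected at construction, never imputed.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.values = np.asarray(self.values, dtype=float)
        n, p = len(self.compound_ids), len(self.descriptor_names)
        if self.values.shape != (n, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} compounds x {p} descriptors"
            )
        dup = _first_duplicate(self.compound_ids)
        if dup is not None:
            raise ValueError(f"duplicate compound ID {dup!r}")
        dup = _first_duplicate(self.descriptor_names)
        if dup is not None:
            raise ValueError(f"duplicate descriptor name {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(
                f"non-finite descriptor value for compound "
                f"{self.compound_ids[i]!r}, descriptor {self.descriptor_names[j]!r}"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def column_index(self) -> dict[str, int]:
        return {name: j for j, name in enumerate(self.descriptor_names)}

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        """Project onto ``names`` (order as given); missing name is a hard error."""
        idx = self.column_index()
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"descriptor(s) not in table: {missing}")
        cols = [idx[n] for n in names]
        return DescriptorTable(list(self.compound_ids), list(names), self.values[:, cols])

    def select_compounds(self, ids: Sequence[str]) -> "DescriptorTable":
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise KeyError(f"compound(s) not in table: {missing}")
        rows = [pos[c] for c in ids]
        return DescriptorTable(list(ids), list(self.descriptor_names), self.values[rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.descriptor_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DescriptorTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))


@dataclass
class ActivityRecord:
    """One compound's logRBA measurements (possibly several, from repeat assays)."""

    compound_id: str
    logrba_values: list[float]

    def __post_init__(self) -> None:
        self.logrba_values = [float(v) for v in self.logrba_values]
        if not self.logrba_values:
            raise ValueError(f"compound {self.compound_id!r}: empty logRBA value list")
        if not all(np.isfinite(self.logrba_values)):
            raise ValueError(f"compound {self.compound_id!r}: non-finite logRBA value")


@dataclass
class AssayRecord:
    """A high-throughput screening outcome for one compound."""

    compound_id: str
    outcome: str

    def __post_init__(self) -> None:
        if self.outcome not in ASSAY_OUTCOMES:
            raise ValueError(
                f"compound {self.compound_id!r}: outcome {self.outcome!r} "
                f"not one of {sorted(ASSAY_OUTCOMES)}"
            )


@dataclass
class LabeledDataset:
    """Descriptor matrix joined to binary binder/non-binder labels.

    ``labels`` is an int array aligned to table rows: 1 = binder, 0 = non-binder.
    """

    table: DescriptorTable
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.table.n_compounds,):
            raise ValueError("label count does not equal compound count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (non-binder) or 1 (binder)")

    @property
    def n_binders(self) -> int:
        return int(self.labels.sum())

    @property
    def n_nonbinders(self) -> int:
        return int((self.labels == 0).sum())

    def subset_rows(self, rows: np.ndarray) -> "LabeledDataset":
        rows = np.asarray(rows)
        ids = [self.table.compound_ids[i] for i in rows]
        table = DescriptorTable(ids, list(self.table.descriptor_names), self.table.values[rows])
        return LabeledDataset(table, self.labels[rows])


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_descriptor_table(
    path, id_column: str = "compound_id", delimiter: str = ","
) -> DescriptorTable:
    """Read a header-ed CSV/TSV of numeric descriptors into a :class:`DescriptorTable`.

    Every non-ID column is parsed as a descriptor.  Duplicate compound IDs and
    non-numeric or missing cells are hard errors naming the offender; file row
    order is preserved.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise ValueError(f"ID column {id_column!r} not found in header of {path}")
    ids = df[id_column].tolist()
    dup = _first_duplicate(ids)
    if dup is not None:
        raise ValueError(f"duplicate compound ID {dup!r} in {path}")
    desc = df.drop(columns=[id_column])
    values = np.empty(desc.shape, dtype=float)
    for j, col in enumerate(desc.columns):
        parsed = pd.to_numeric(desc[col], errors="coerce")
        bad = parsed.isna() | ~np.isfinite(parsed.to_numpy(dtype=float))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric or missing value {desc[col].iloc[i]!r} for "
                f"compound {ids[i]!r}, descriptor {col!r} in {path}"
            )
        values[:, j] = parsed.to_numpy(dtype=float)
    return DescriptorTable(ids, list(desc.columns), values)


def write_descriptor_table(
    table: DescriptorTable, path, id_column: str = "compound_id", delimiter: str = ","
) -> None:
    df = table.to_dataframe()
    df.index.name = id_column
    df.to_csv(path, sep=delimiter, float_format="%.10g")


def read_activity_records(path, delimiter: str = ",") -> list[ActivityRecord]:
    """Read ``compound_id,logrba`` rows (one row per measurement) into records."""
    df = pd.read_csv(path, sep=delimiter, dtype={"compound_id": str})
    for col in ("compound_id", "logrba"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    records = []
    for cid, grp in df.groupby("compound_id", sort=False):
        records.append(ActivityRecord(str(cid), [float(v) for v in grp["logrba"]]))
    return records


def read_assay_records(path, delimiter: str = ",") -> list[AssayRecord]:
    """Read ``compound_id,outcome`` rows into assay records."""
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    for col in ("compound_id", "outcome"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    return [AssayRecord(str(r.compound_id), str(r.outcome)) for r in df.itertuples()]


def label_compound(record: ActivityRecord, threshold: float = LOGRBA_THRESHOLD) -> str:
    """Label one compound from its logRBA values.

    A single value labels the compound directly: binder iff logRBA >= threshold.
    Several values are labelled individually and decided by strict majority; an
    exact tie returns ``"excluded"`` — an ambiguous label would corrupt training.
    """
    calls = [v >= threshold for v in record.logrba_values]
    n_binder = sum(calls)
    n_non = len(calls) - n_binder
    if n_binder > n_non:
        return BINDER
    if n_non > n_binder:
        return NON_BINDER
    return EXCLUDED


def assemble_dataset(
    table: DescriptorTable,
    records: Sequence[ActivityRecord],
    threshold: float = LOGRBA_THRESHOLD,
) -> LabeledDataset:
    """Join activity records to the descriptor table, dropping tie-excluded compounds.

    Every record's compound must be present in the table (exact, case-sensitive
    ID match).  Emits a per-class count summary to the module logger.
    """
    pos = {c: i for i, c in enumerate(table.compound_ids)}
    rows: list[int] = []
    labels: list[int] = []
    n_excluded = 0
    for rec in records:
        if rec.compound_id not in pos:
            raise KeyError(f"compound {rec.compound_id!r} absent from descriptor table")
        call = label_compound(rec, threshold)
        if call == EXCLUDED:
            n_excluded += 1
            log.info("compound %s excluded: tied logRBA consensus", rec.compound_id)
            continue
        rows.append(pos[rec.compound_id])
        labels.append(1 if call == BINDER else 0)
    if not rows:
        raise ValueError("no compounds remain after consensus exclusion")
    ids = [table.compound_ids[i] for i in rows]
    sub = DescriptorTable(ids, list(table.descriptor_names), table.values[rows])
    ds = LabeledDataset(sub, np.array(labels))
    log.info(
        "assembled dataset: %d binders, %d non-binders, %d excluded",
        ds.n_binders, ds.n_nonbinders, n_excluded,
    )
    return ds
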