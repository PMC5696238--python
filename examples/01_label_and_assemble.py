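"""Label compounds binder/non-binder from logRBA values and assemble a training set.

A compound is a binder when logRBA >= -5 (inclusive); compounds with several
measurements are decided by strict majority, and exact ties are excluded.
"""

import logging

from dfqsar import ActivityRecord, label_compound, assemble_dataset, generate_dataset
from dfqsar.synthetic import scaled_config

logging.basicConfig(level=logging.INFO, format="%(message)s")

examples = [
    ActivityRecord("estradiol-like", [-1.2]),
    ActivityRecord("boundary-case", [-5.0]),
    ActivityRecord("weak-binder", [-5.0001]),
    ActivityRecord("replicated", [-4.0, -6.0, -4.5]),
    ActivityRecord("conflicted", [-4.0, -6.0]),
]
for rec in examples:
    print(f"{rec.compound_id:15s} logRBA={rec.logrba_values} -> {label_compound(rec)}")
print("(-5.0 is a binder because the threshold is inclusive; the 2-valued tie is excluded)\n")

# joining labels to a descriptor table drops excluded compounds and keeps row alignment
dataset, _ = generate_dataset(scaled_config(seed=0))
records = [
    ActivityRecord(cid, [-4.0 if y else -6.0])
    for cid, y in zip(dataset.table.compound_ids, dataset.labels)
]
assembled = assemble_dataset(dataset.table, records)
print(f"assembled training set: {assembled.n_binders} binders, "
      f"{assembled.n_nonbinders} non-binders "
      f"({assembled.n_nonbinders / assembled.table.n_compounds:.1%} of compounds)")
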