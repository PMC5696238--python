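"""Remove low-information descriptors before training.

A descriptor whose single most frequent value dominates more than 95% of the
compounds (or is outright constant) cannot support useful tree splits and is
dropped.  The kept-column list is reusable on application tables.
"""

from dfqsar import filter_low_information, apply_filter, generate_dataset
from dfqsar.synthetic import scaled_config

dataset, _ = generate_dataset(scaled_config(seed=0))
filtered, report = filter_low_information(dataset.table, dominance_threshold=0.95)
print(f"{dataset.table.n_descriptors} descriptors in, "
      f"{len(report.kept_names)} kept, {len(report.removed_names)} removed "
      f"(near-constant columns: {report.removed_names})")

# the same kept-column list projects an application table identically
projected = apply_filter(dataset.table, report)
assert projected.descriptor_names == filtered.descriptor_names
print("application table projected onto the identical kept-column list "
      "(no train/apply column mismatch)")
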