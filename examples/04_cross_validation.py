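"""Repeated 5-fold cross-validation on the imbalanced synthetic benchmark.

Metrics are computed on the pooled out-of-fold predictions of each iteration,
so specificity stays defined even when a single fold draws no non-binders.
With 4% non-binders the model is heavily biased toward the binder class:
sensitivity stays near 1 while specificity is modest, exactly the imbalance
signature the original study reports.
"""

from dfqsar import cross_validate, generate_dataset
from dfqsar.synthetic import scaled_config

dataset, _ = generate_dataset(scaled_config(seed=1))
result = cross_validate(dataset, k=5, iterations=10, base_seed=101)

print(f"{result.n_iterations} iterations x 5 folds = {result.n_models} models\n")
for name, stats in result.summary().items():
    print(f"{name:18s} {stats['mean']:.3f} +/- {stats['sd']:.3f}")
print("\nsensitivity >> specificity: the 96%-binder majority dominates training,")
print("mirroring the high-sensitivity / low-specificity profile of the study model")
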