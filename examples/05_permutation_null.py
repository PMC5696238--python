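"""Label-permutation (y-scrambling) null distribution.

Scrambling the labels and rerunning the full 5-fold CV pipeline estimates the
chance-correlation baseline.  Raw accuracy stays high (the permuted data are
still 96% binders) but MCC centres on 0 and balanced accuracy on 0.5 — the
fingerprint of a model with no real signal.
"""

from dfqsar import cross_validate, generate_dataset, permutation_test
from dfqsar.synthetic import scaled_config

dataset, _ = generate_dataset(scaled_config(seed=1))
null = permutation_test(dataset, replicates=25, k=5, base_seed=900)
cv = cross_validate(dataset, k=5, iterations=5, base_seed=101)

print("metric              permuted        real labels")
for name in ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "mcc"):
    p = null.summary()[name]
    r = cv.summary()[name]
    print(f"{name:18s} {p['mean']:6.3f}+/-{p['sd']:.3f}   {r['mean']:6.3f}+/-{r['sd']:.3f}")
print("\npermuted MCC ~ 0 and balanced accuracy ~ 0.5 reproduce the expected null;")
print("the gap to the real-label run shows the model is not a chance artefact")
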