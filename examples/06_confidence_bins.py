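"""Prediction-confidence analysis of cross-validation output.

Confidence = |P - 0.5| / 0.5.  Out-of-fold predictions are placed in ten
equal-width confidence bins; accuracy rising with the bin index means the
statistic can serve as an applicability guide in deployment.
"""

from dfqsar import bin_predictions, cross_validate, generate_dataset
from dfqsar.synthetic import scaled_config

dataset, _ = generate_dataset(scaled_config(seed=1))
cv = cross_validate(dataset, k=5, iterations=10, base_seed=101)
probs, actual = cv.pooled_predictions()
report = bin_predictions(probs, actual, n_bins=10)

print("bin        n   accuracy")
for b in report.bins:
    acc = "   --" if b.metrics is None else f"{b.metrics.accuracy:.3f}"
    print(f"[{b.low:.1f},{b.high:.1f})  {b.n:5d}  {acc}")
rho = report.spearman_confidence_accuracy()
print(f"\nSpearman(bin index, bin accuracy) = {rho:.2f}: higher-confidence "
      "predictions are more accurate")
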