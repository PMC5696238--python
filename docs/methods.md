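# Methods

## Problem and endpoint

The package classifies chemicals as estrogen-receptor-beta binders or
non-binders from precomputed numeric molecular descriptors.  The training
endpoint derives from competitive-binding assays: logRBA, the log10 relative
binding affinity versus a reference ligand.  A compound is a binder iff
logRBA ≥ −5; the boundary is inclusive.  Compounds carrying several
measurements are labelled per measurement and decided by strict majority.
An exact tie (an even number of conflicting values) is *excluded* from
training and logged: the consensus rule gives no basis for either label, and
an ambiguous label would corrupt an endpoint that is 98.8% one class.
Compound IDs match by exact, case-sensitive string equality.

## Descriptor filtering

Descriptors whose single most frequent value occurs in strictly more than a
`dominance_threshold` fraction of training compounds are removed before
training; constant columns are removed at any threshold.  The default
threshold is 0.95.  "The same value" means exact floating-point equality —
descriptor generators emit discretised, typed values, and epsilon-bucketing
would silently merge distinct levels.  The filter is fit on the training
table only; the kept-column list is serialised (`FilterReport`) and applied
verbatim to application tables, which prevents leakage and train/apply
column mismatch.  Missing descriptor values are rejected everywhere, never
imputed: complete tables are the input contract, and imputation would change
the feature space undetectably.

## The Decision Forest

Trees are grown greedily: at each node, every descriptor still in the pool
is scanned for the midpoint threshold between adjacent distinct sorted
values that maximises Shannon-entropy information gain, subject to both
children holding at least `min_leaf` samples.  Growth stops at class purity,
at `min_leaf`, at an optional `max_depth` (default unlimited — deep trees
are a defining DF trait), or when no split has strictly positive gain.
Leaves store the binder fraction of their training samples.

Forest construction is sequential: after each tree, the descriptors it used
in split nodes leave the pool, so tree pools are pairwise disjoint by
construction (an invariant the model object enforces).  A candidate tree is
kept only if it raises the consensus *training balanced accuracy* by more
than `improvement_epsilon` (default 0); a non-improving candidate is
discarded and training stops.  Balanced accuracy is the improvement metric
because plain accuracy is saturated near 0.99 by the majority class and
would stop after one tree regardless of signal.  Training also stops at
`max_trees` (default 10), on pool exhaustion, or when the candidate
degenerates to a single leaf.  The consensus probability is the unweighted
arithmetic mean of per-tree leaf fractions; no tree weighting is applied.
No class weighting or resampling counteracts the imbalance — the modelled
protocol leaves the bias in, and the high-sensitivity/low-specificity
profile is part of the behaviour being reproduced.

Determinism: training involves no random draws.  Gain ties between
thresholds resolve to the smallest threshold; ties between descriptors
resolve to table column order.  Identical data and configuration therefore
yield byte-identical serialised models.

Numerical notes: entropies are computed with the 0·log 0 = 0 convention;
`best_split` reports the gain-maximising admissible threshold even when that
maximum is zero, while tree growth treats zero gain as "no admissible
split" and stops — splitting on zero gain would grow structure that encodes
nothing.

## Validation protocol

One cross-validation iteration partitions compounds uniformly at random into
k = 5 near-equal folds (unstratified — the divisions are plain random; with
~1% non-binders a fold can lack negatives, and the large specificity spread
this produces is part of the modelled protocol; a class-stratified division
is available behind a non-default flag).  Each fold is predicted by a forest trained on the other
four; metrics are computed on the *pooled* out-of-fold predictions of the
iteration rather than averaged over folds, so specificity remains defined
when a fold has no negatives.  Should a *training* split lose a class
entirely, that model falls back to a prior-fraction leaf and the iteration
is flagged.  Iterations repeat with fresh random divisions (1000 in the
modelled protocol; desk-scale runs here use 10–20).

The permutation test refits the identical pipeline on label-permuted copies
of the dataset: replicate r permutes the label vector (class counts
preserved by construction) and runs one full 5-fold CV.  Seeding is
laddered: iteration/replicate i draws from a generator seeded
`base_seed + i`, making every iteration independently reproducible.

Prediction confidence |P − 0.5|/0.5 is binned into ten equal-width bins over
[0, 1] ("even bins" read as even width), left-closed right-open with the
final bin closed so confidence 1.0 is counted; each bin is scored with the
full metric set.

Descriptor importance is frequency of use: a descriptor counts as used in a
model iff it appears in at least one split node of any of the model's trees
(pool membership alone reflects ordering, not contribution).  Descriptors
used in strictly more than 90% of CV models form the informative set.

Concordance between two experimental label sets treats one labelling as a
prediction of the other; the agreement fraction is the accuracy of the
resulting 2×2 table.  The binding database serves as the reference, so with
shared compounds that are all database binders the negative row is empty and
specificity/balanced accuracy are reported as undefined rather than forced
to a number.  Metrics with zero denominators are undefined throughout;
an MCC whose denominator contains a zero factor is reported as 0 with an
explicit flag (the convention under which a one-sided classifier has zero
correlation).  Printed percentages round half-up to one decimal.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
chemistry.  Defaults mirror the modelled corpus: 2462 binders, 30
non-binders, 447 descriptors, 18 informative, 10% near-constant columns (to
exercise the dominance filter), effect size 1.5.

Informative descriptors use bounded-support uniform class-conditionals.
Binders form a wide cloud (standard deviation `binder_dispersion × noise_sd`,
dispersion ratio 1.5) centred at zero; non-binders form a compact niche
(standard deviation `noise_sd`) centred at `effect_size × pooled sd`, with a
random sign per descriptor — a small, dense class at the edge of a large,
diffuse one, the chemical-space structure observed for this endpoint.
`effect_size` is the standardized mean class separation (mean difference
over pooled SD).  Bounded supports matter: real descriptors are physically
bounded counts, indices and volumes, and it is the bounded tail — the region
beyond the majority class's range — that lets an axis-aligned threshold
reach a minority-pure region at a 98.8%/1.2% imbalance.  An unbounded
normal family with the same standardized separation leaves no axis interval
where non-binders outnumber binders, making the planted signal invisible to
any tree learner (verified against independent tree implementations) even
though it remains linearly recoverable.  Non-informative descriptors are
class-independent Gaussian noise.

Two desk-scale presets fix the study conditions for experiments and tests:

- `scaled_config()` — 480 binders / 20 non-binders (4% negatives), 50
  descriptors, 18 planted (the generator default count): the imbalanced
  benchmark for CV, permutation-null and confidence analyses.
- `sparse_signal_config()` — same scale with 3 planted descriptors, the
  modelled corpus's 18-of-447 informative proportion: the regime for
  descriptor-recovery analyses.  The distinction is structural: the DF's
  mean consensus plus strict-improvement stopping caps forests at 2–3 trees
  (~9–12 split descriptors per model), so a planted set can only be
  recovered *in full* by the >90%-frequency rule when its size is within
  that per-model capacity.  Large interchangeable planted sets spread usage
  across models and no single descriptor clears 90%; the corpus's own
  high-frequency descriptors are complementary real features, not
  exchangeable copies.

The logRBA record generator emits compounds with one or three measurements
straddling the threshold, with at least two measurements on the consensus
side, plus the ground-truth label for self-consistency checks.

What passing on synthetic data does and does not show: the generator
reproduces the imbalance, the planted-signal recoverability and the
wide-binder/compact-non-binder geometry, but not descriptor correlation
structure, discreteness, heavy tails, or assay noise of real
descriptor tables.  Results on it validate the pipeline's mechanics and
statistical behaviour, not chemical accuracy.

## Problem sizes

Desk-scale experiments use 500-compound benchmarks, 10–20 CV iterations and
25–100 permutation replicates; the acceptance script runs 100 permutation
replicates of 5-fold CV (≈500 forest trainings).  These sizes give stable
means (null balanced accuracy varies by well under a percentage point across
seeds) while keeping any single experiment in the tens of seconds.

## Known limitations

- Out-of-fold specificity at 4% negatives is intrinsically noisy (4 negatives
  per test fold); per-iteration specificity has a spread of ~0.1.
- The DF stopping rule caps forests early on separable data; consequently
  per-model descriptor usage is small, and frequency-based importance should
  be interpreted against model capacity (see above).
- Concordance with an empty negative row cannot yield a balanced accuracy;
  it is reported undefined by design.
- Descriptor computation from structures (SDF/SMILES) is out of scope; the
  package consumes precomputed tables.
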