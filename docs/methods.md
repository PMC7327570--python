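# Methods

This note documents the models and procedures implemented in `sigsift`, the
parameters that matter, the synthetic data the package validates itself on,
and the numerical and design choices made where more than one reasonable
option existed.

## The discovery funnel

The package addresses a standard problem in blood-transcriptome diagnostics:
given a genes × samples expression matrix and a K-class label per sample,
find a compact gene set that discriminates the classes, and characterize its
biology. The funnel narrows the gene set in four stages — all-relevant
filtering, importance ranking, ranking cutoff, and cross-validated prefix
selection — each of which only ever removes genes, so the output of every
stage is a subset of its input.

### Quantile normalization

Samples from different array platforms carry different intensity
distributions. Quantile normalization replaces each value by the reference
value at its within-column rank, where the reference is the vector of row
means of the column-sorted matrix. Tied values within a column receive the
mean of the reference values spanned by the tie — the observable convention
of the classic `normalize.quantiles` routine. Consequences worth knowing:

- A constant additive offset on any subset of samples is removed exactly:
  the normalized matrix equals the batch-free normalization plus a constant
  (`fraction-shifted × shift`) everywhere. Tests assert this identity to
  1e-9.
- Idempotence and "all columns share one sorted vector" hold exactly on
  tie-free data; with ties the averaged values perturb both properties
  slightly. This is inherent to the tie convention, not an implementation
  artifact.
- Normalization is applied once, jointly across all samples after the
  platform merge; merging (`intersect_genes`) keeps the lexicographically
  sorted common genes and concatenates samples.

### Boruta all-relevant filtering

Each iteration augments the data with one shadow per gene — that gene's
values permuted across samples — fits a random forest (100 trees,
impurity-decrease importance) on real-plus-shadow features, and scores a
*hit* for every undecided gene whose importance exceeds the maximum shadow
importance. After each iteration a two-sided binomial test at level `alpha`
(default 0.05) on each undecided gene's hit count confirms genes hitting
significantly above half and rejects genes hitting significantly below;
genes still undecided after `max_iter` (default 100) iterations are
*tentative* and excluded from the confirmed set, which is the conservative
reading when a single confirmed count is the stage's contract.

Two choices depart from the most common reference implementations, both for
null-calibration reasons measured during development:

- **The shadow pool is all original genes, every iteration**, not just the
  not-yet-rejected ones. With low-variance impurity importances, a shrinking
  pool lets a gene that merely correlates with the labels by chance beat the
  maximum of a handful of fresh shadows nearly every round and accumulate
  hits to confirmation. Against the maximum over all *d* shadows — the same
  order statistic that made the gene look good in the first place — such a
  gene wins only about half the time and correctly stays tentative. On
  pure-noise data (500 genes, four classes of 30, alpha = 0.01) the fixed
  pool yields zero confirmations in 20/20 replicates; the shrinking pool
  confirmed 1–6 false genes per replicate.
- **The Bonferroni correction divides by the number of genes entering the
  run**, held constant across iterations (the all-attribute adjustment),
  rather than by the shrinking number of undecided genes, which would loosen
  the test exactly when the null is weakest.

Rejected genes do leave the forest's real-feature side, so iteration cost
drops sharply once the bulk of a null background is rejected; the loop stops
early when no genes remain undecided.

### Monte-Carlo feature selection

`s` subsets ("projections") of `m` genes are drawn uniformly without
replacement; for each subset `t` entropy decision trees (unlimited depth,
minimum 2 samples to split) are grown, each on a fresh stratified draw of
`split_fraction` of the samples, and evaluated on the held-out remainder.
Per tree the package records its class-balanced accuracy wAcc (the mean of
per-class recalls — a plain accuracy would be dominated by the largest class
under cohort imbalances like 75/122/71/311), its training-sample count, and
for every internal node the splitting gene, entropy information gain, and
node sample count. The relative importance of gene *g* is

    RI(g) = Σ_τ (wAcc_τ)^u · Σ_{nodes of τ on g} IG · (node samples / tree training samples)^v

summed over all s·t trees, zero for genes never split on. Defaults: u = v = 1,
`split_fraction` = 0.66, t = 5, and the derived sizes m = max(⌈0.05 d⌉, 5),
s = ⌈15 d / m⌉ so each gene is expected in ~15 projections. Because RI is a
plain sum over trees it is additive over disjoint tree sets, and u = v = 0
reduces it to a raw information-gain total — both are tested against
independent oracles. Ranking is by descending RI with lexicographic gene-ID
tie-break for determinism.

Projection size trades off two errors: large m lets same-class planted genes
compete inside a subset (the tree picks one, halving the loser's RI), while
tiny m weakens the trees. When an analysis hinges on the stability of the
*weakest* interesting gene's RI, raising `s` well above the default (so each
gene lands in ≥ 30 projections) is the effective lever; the validation suite
uses s = 300 for its 80-gene cutoff study for exactly this reason.

**Top-ranking cutoff.** How deep the ranking carries signal is estimated by
a label-permutation null: the full MCFS computation is re-run `n_perm` times
on permuted labels, the 95th percentile of the resulting maximal RI is the
threshold, and the cutoff is the number of leading genes above it. On pure
noise this is ≈ 0 by construction (the observed maximum exceeds the null
maxima's quantile ~5% of the time). A `fixed_k` override exists for
replicating an externally chosen list length.

### Incremental feature selection

For k on a grid (every k up to 200, then every 5th, in the end-to-end
pipeline; configurable), the top-k genes feed a linear SVM (C = 1,
one-vs-rest) evaluated by leave-one-out cross-validation; genes are
standardized inside each training fold and the held-out sample transformed
with the fold's parameters, so no information leaks into the scaling. The
signature is the smallest k attaining the maximum accuracy — parsimony on
ties — and is summarized by a predicted × actual confusion matrix whose
per-class accuracies are diagonal over column sums (displayed at 3
decimals); a class absent from the actual samples yields an undefined (NaN)
accuracy and a warning.

A consequence of the parsimony rule worth stating plainly: when individual
genes carry strong effects (≥ 3 noise-SD), LOOCV accuracy saturates at 1.0
after a handful of genes, and the selected k* is then *smaller* than the
number of genes that genuinely carry signal — the sweep measures sufficiency
for classification, not completeness of the relevant set. Completeness is
Boruta's job, and on the same data Boruta's confirmed set does contain all
planted genes. Signature recovery in the "contains ≥ 80% of the planted
genes" sense is only achievable when per-gene effects are weak enough that
accuracy keeps improving out to the full planted set.

### Enrichment

Over-representation of a query gene list in each set of a GMT collection is
the upper-tail hypergeometric probability P(X ≥ k) with universe N = the
genes entering the analysis (not the genome), set size K counted after
intersecting the set with the universe, and query size n after dropping
(with a logged warning) query genes outside the universe. FDR is
Benjamini–Hochberg within one collection per call; callers wanting
per-category adjustment (KEGG vs GO branches) call once per collection.
P-values of discrete tests are conservative: under a random query their mean
is slightly above 0.5 and their distribution matches the exact discrete null
law, which is what the calibration test checks.

## The synthetic-data generator

The generator emulates the features of a multi-platform case/control blood
cohort that the pipeline's correctness depends on: a K-class design with
unequal class sizes (defaults 75/122/71/311), a small planted set of
class-discriminating genes inside a large irrelevant background, per-sample
platform offsets, and Gaussian measurement noise.

- Background: each gene draws a baseline from N(8, 2) (a log2-intensity-like
  scale) and i.i.d. Gaussian noise with SD `noise_sd` (default 1) across
  samples.
- Planted genes: gene *i* of the informative set has its mean raised by
  `effect_size × noise_sd` in one designated class, cycling through the
  classes so every class owns discriminating genes.
- Batch: a `batch_fraction` of *each class* is assigned to the second
  platform (crossed with class, so batch never confounds class and
  normalization is testable) and receives a constant `batch_shift` on all
  genes.
- Randomness: one root seed is split into independent streams for baselines,
  noise and batch assignment; identical configs are bitwise-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: probe-level artifacts, missing values,
platform-specific probe sets, heavy-tailed or gene-correlated noise,
class-dependent covariance, or label noise. Real cohorts have weaker,
partially redundant, correlated effects; recovery rates here are best-case
calibrations of the machinery, not forecasts of field performance.

## Validation problem sizes

The validation suite exercises the study conditions at these sizes, chosen
to make each probabilistic claim sharp at desk scale: null calibration on
500 genes × 120 samples over 20 replicates at alpha = 0.01; recovery on
2,000 genes × 160 samples with 20 planted genes at 3 noise-SD over 3
replicates; oracle equivalence of the RI formula on a hand-built 2-tree
instance (≤ 1e-12), of the hypergeometric tail against exhaustive
enumeration for every universe ≤ 30, and of BH against its step-up
definition on 100 random vectors.

## The end-to-end pipeline

Stage seeds derive from `sha256(root_seed:stage_name)`, so any stage can be
re-run standalone from the manifest (which records parameters, seeds and
SHA-256 of every artifact) and reproduce its outputs byte-for-byte. Two
degenerate-input fallbacks keep a null dataset reportable end to end: if
Boruta confirms nothing, MCFS ranks all genes; if the permutation cutoff is
0, the IFS sweep still covers the top min(20, N) genes so the report carries
a (near-chance) accuracy. Note that the reported accuracy of a null run is
the maximum over the sweep and therefore sits above chance by selection —
about 0.4–0.5 for four balanced classes of 12 — which is expected behaviour
of a maximum, not signal.

## Known limitations

- Impurity-based importance inherits its known bias toward
  many-valued features; with continuous expression on all genes this is
  uniform, but mixed-type inputs would need permutation importances.
- LOOCV at n in the hundreds is O(n) SVM fits per curve point; the strided
  default grid keeps full sweeps tractable, at the cost of locating the peak
  only to stride resolution beyond k = 200.
- The permutation cutoff re-runs the entire MCFS ensemble per permutation;
  its cost is `n_perm` × the ranking cost.
- BH adjustment is not idempotent on already-adjusted values (the m/rank
  factor reapplies); only constant vectors are fixed points.
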