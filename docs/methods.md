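# Methods

This note records the model implemented by `coexbuild`, the reasoning
behind its parameter defaults and the places where a design choice had
more than one defensible answer.

## 1. Pipeline model

### 1.1 Input and preprocessing

The unit of input is a gene × sample matrix of non-negative RNAseq counts
(`ExpressionMatrix` with `scale="counts"`). Preprocessing is a fixed
chain:

1. **Sample filter.** A sequencing run is discarded when its total count
   is *strictly below* `min_total_counts` (default 2 000 000). A run
   summing to exactly the threshold is kept. The rule is a discard rule,
   so boundary semantics matter for reproducibility and are pinned by
   tests.
2. **Gene filter.** After the sample filter, a gene is discarded when its
   mean count *over the surviving samples* is strictly below
   `min_mean_count` (default 30). Ordering matters: a gene's mean is
   evaluated on the filtered compendium, not the raw one.
3. **Log transform.** log₂(x + c) with pseudo-count c = 0.125. The
   pseudo-count keeps zeros finite (log₂0.125 = −3) while barely
   perturbing counts ≥ 30, the smallest a surviving gene can average.
4. **Gene centering.** Each gene's row is shifted to mean zero. PCA and
   Pearson correlation both assume this; `pca_truncate` rejects
   uncentered input rather than silently centering, so the caller's data
   model stays explicit.

Batch/platform correction is deliberately out of scope: compendia differ
too much for one built-in method to be honest. `apply_corrected_matrix`
accepts an externally corrected matrix of identical shape and swaps it in
after the log step. Microarray data, which arrives already normalized and
log-scale, enters the pipeline at the centering step with
`scale="log2"`.

### 1.2 PCA truncation

X = UΣVᵀ via `numpy.linalg.svd`. Components with singular values below a
numeric-rank tolerance (machine-epsilon scaled by the largest singular
value and matrix size) are dropped, then at most `max_pcs` (default 1000)
strongest components are kept. Truncation denoises: trailing components
of a large compendium are dominated by technical noise, and capping at
1000 also bounds the ensemble's per-repetition cost regardless of
compendium size.

### 1.3 PC-subsampling ensemble

For each of `n_repetitions` (default 1000) repetitions, a uniform random
subset of k = max(1, round(`subsample_fraction` × n_kept)) components is
drawn (default fraction 0.10), expression is reconstructed from that
subset alone, reconstructed rows are re-centered and unit-normalized, and
the gene × gene Pearson matrix is formed. Genes with zero variance in a
reconstruction get NaN correlations in that repetition (with a warning)
and are simply skipped by the aggregator's per-entry counts.

Each repetition draws its generator from
`numpy.random.SeedSequence(seed).spawn(n_repetitions)`, so results are
bit-reproducible given (seed, reps, fraction) and independent of
execution order.

Why subsample components at all? A single Pearson matrix is hostage to
whatever dominates the top of the spectrum — batch structure, one large
tissue block. Averaging over random spectral subsets asks which gene
pairs correlate *robustly across many views* of the compendium, which is
the property coexpression analysis actually wants.

### 1.4 Mutual Rank

Within each repetition the correlation matrix is converted to Mutual
Rank: rank(a→b) is the 1-based position of b among all other genes
ordered by descending correlation with a (average ranks on ties, self
excluded), and MR(a,b) = √(rank(a→b)·rank(b→a)). MR is scale-free —
it survives monotone distortions of the correlation and equalizes
hub-gene effects, because a pair is strong only if each gene ranks the
*other* highly. Valid off-diagonal MR lies in [1, n−1]; the diagonal
carries the sentinel 0 ("self", never a valid rank).

### 1.5 Aggregation

Per-entry, repetition MR values are mapped to (0, 1) by the affine map

p = (MR − 0.5) / (n − 1),

logit-transformed, averaged (NaN entries excluded, per-entry counts),
then mapped back through the sigmoid and the inverse affine map, and the
result is symmetrized and clipped to [1, n−1].

Two choices here deserve justification:

* **Logit rather than arithmetic averaging.** The interesting signal is
  at the extremes — MR near 1. An arithmetic mean lets a few noisy
  large-MR repetitions wash out consistent near-1 values; the logit
  stretches both tails so consistency near the boundary is preserved.
* **The half-step affine map.** The obvious map (MR−1)/(n−2) sends the
  boundary values MR=1 and MR=n−1 to exactly 0 and 1, where the logit
  diverges, forcing an arbitrary ε-clip — and then an ensemble of
  identical matrices no longer aggregates to itself at the boundary.
  The half-step map (MR−0.5)/(n−1) places every valid MR strictly inside
  (0, 1) (p ranges over [0.5/(n−1), (n−1.5)/(n−1)]), needs no clipping
  on valid input, and makes "identical repetitions aggregate to
  themselves" an exact identity, which the test suite asserts at 1e-8.
  It is the same continuity correction used when mapping ranks to
  quantiles. The map is a pluggable pair of functions
  (`mr_to_unit`/`unit_to_mr`), so an alternative convention is a two-line
  change.

With fraction 1.0 and a single repetition the whole construction
provably collapses to classic Pearson Mutual Rank; this is both a test
and the recommended sanity check on new data.

## 2. Evaluation: the pathway score

Functional coherence is scored against a pathway annotation (GMT). After
intersecting with the platform's genes, pathways with fewer than 2 or at
least `max_pathway_size` (default 50) genes are dropped — very large
pathways are too generic to define meaningful pairwise coupling. Every
unordered pair of annotated genes is labeled positive if the two genes
share at least one surviving pathway, negative otherwise. A positive
pair's weight is the maximum over shared pathways of 1/|pathway|: a pair
coupled through a 5-gene complex should count for more than one sharing
a 49-gene generic set. Negative pairs have weight 1.

The score is the area under the weighted ROC curve (pairs ranked by
ascending MR; ties collapsed into single ROC vertices; trapezoidal area
with segment clipping at the boundary) up to `fpr_max` = 0.01, then
standardized following McClish (1989):

score = ½ · (1 + (A − A_min)/(A_max − A_min)),  A_min = fpr_max²/2, A_max = fpr_max.

Only the extreme early part of the ranking matters in practice — nobody
follows up more than the top fraction of a genome² pair list — hence the
1% FPR cap. Raw partial areas are scale-awkward (a random ranking scores
fpr_max²/2 ≈ 5·10⁻⁵), so the standardization maps chance to 0.5 and
perfection to 1.0, keeping the familiar AUROC reading. This is the same
convention as scikit-learn's `roc_auc_score(..., max_fpr=...)`, which the
test suite uses as an independent oracle in the unweighted case. The raw
and raw/fpr_max scales remain available via `normalize="raw"` and
`"fraction"`.

## 3. Cross-platform comparison

* **Similarity.** For each pair of platforms, MR values are collected
  over all gene pairs whose genes exist in every platform under the
  supplied one-to-one ortholog maps (anchored in the first platform's
  namespace), and Spearman's ρ is computed. Spearman, not Pearson: MR is
  ordinal and heavy-tailed, and only the ordering of pair strengths is
  comparable across platforms.
* **Clustering.** Complete linkage on the distance 1 − ρ;
  complete linkage keeps clusters compact, so a cluster certifies that
  *every* member pair is similar. The dendrogram can be serialized to
  newick.
* **Supportability.** For a guide gene g in platform A and a reference
  platform B containing an ortholog of g, COXSIM compares the top
  k = ⌈`top_fraction` × universe⌉ coexpressed genes of g in A and of its
  ortholog in B over the shared (ortholog-mapped) gene universe minus
  the guide itself:

  COXSIM = Σ_{shared genes} w(rank_A) · w(rank_B) / Σ_{r=1..k} w(r)²,
  w(r) = 1/log₂(r+1),

  i.e. a discounted-cumulative-gain-style overlap normalized so identical
  lists score 1. maxCOXSIM is the maximum over references; genes with no
  ortholog anywhere are reported `missing` (level −1). maxCOXSIM values
  are discretized into quartile levels 0–3 (boundary ties fall to the
  lower level), a deliberately coarse scale: the absolute value depends
  on universe size and top_fraction, but the within-study ranking is
  stable.

  The default `top_fraction` = 0.01 needs a shared universe of at least
  100 genes to give a non-trivial top list; `supportability` enforces
  this.

## 4. Synthetic data

`ModuleSpec` defines a latent-factor Gaussian generator: each planted
module has one latent factor per sample, and a member gene is
a·factor + noise_sd·ε with a = √(ρ/(1−ρ)), giving expected within-module
Pearson correlation ρ (`within_corr`). Background genes are pure noise.
`scale="counts"` runs the signal through Poisson(2^(baseline + signal))
to exercise the count-side preprocessing. `generate_annotation` emits one
pathway per module (optionally partial coverage); `generate_platform_family`
produces platforms sharing a controlled fraction of modules, with private
modules placed on permuted free slots and one-to-one ortholog maps.

Scope and limitations: modules are rank-1 (one factor each), noise is
homoscedastic Gaussian, and there is no batch structure, library-size
variation or overdispersion beyond Poisson. This is enough to verify the
pipeline's statistical behavior and calibrate its scores, not to imitate
a real compendium's difficulty.

## 5. Study-scale parameters used in tests and the acceptance script

Production defaults (1000 repetitions, fraction 0.10, 1000 PCs) assume a
compendium with thousands of samples. The test and acceptance studies run
on ~200-gene, ~200-sample synthetic matrices, where those defaults are
statistically mis-sized, not merely slow: a rank-1 planted module
concentrates its variance in roughly one principal component, so a
repetition carries the module's signal only if its PC draw includes that
component — probability ≈ `subsample_fraction`. The number of
signal-bearing repetitions is therefore ≈ Binomial(reps, fraction): at
production settings E = 1000 × 0.10 = 100, comfortably above noise; at
50 × 0.10 it is 5, and the logit mean is noise-dominated. The desk-scale
profile used throughout the tests, **50 repetitions at fraction 0.5**,
restores E = 25 signal-bearing repetitions while keeping each study under
a few seconds. This is a power calculation about the study design, made
before looking at outcomes; the production defaults in
`coexbuild.config.PipelineConfig` are unchanged.

Other fixed study conditions: planted-module recovery uses two 10-gene
modules (ρ = 0.8) among 180 background genes over 200 samples — 200
samples rather than 100 because the pathway-score study has only 100
negative pairs, and at 1% FPR the partial area then reduces to the
weighted true-positive rate above the single strongest negative pair,
which is fragile unless planted correlations are tight. The
supportability study uses 12 modules × 10 genes + 30 background (150
genes) so the default top_fraction = 0.01 applies without modification.

## 6. Numerical choices

* SVD, rank ties, Spearman, linkage, Mann-Whitney: `numpy`/`scipy`
  primitives (`linalg.svd`, `stats.rankdata(method="average")`,
  `stats.spearmanr`, `cluster.hierarchy.linkage`), not reimplemented.
  The package's own contributions — MR, the subsampling ensemble, logit
  aggregation, the weighted partial AUROC and COXSIM — are implemented
  here and cross-checked against independent oracles in the tests.
* Correlations are clipped to [−1, 1] after unit-normalized dot products
  to absorb rounding before ranking.
* All randomness flows from `numpy.random.SeedSequence` spawning; no
  global RNG state is touched.
* The aggregate is clipped back to the valid MR range [1, n−1] and
  symmetrized; asymmetries can only arise from floating-point
  non-associativity and are at the 1e-12 level.

## 7. Known limitations

* No built-in batch correction (by design; see §1.1).
* The weighted pAUROC's weighting applies to positives only; alternative
  schemes (weighting negatives by annotation confidence) are not
  implemented.
* Supportability's quartile levels are relative to the analyzed gene set,
  so levels are not comparable across runs with different universes.
* The synthetic generator's modules are disjoint; overlapping pathway
  structure is not modeled.
* Platform storage is one HDF5 file per platform; there is no compendium
  database layer.
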