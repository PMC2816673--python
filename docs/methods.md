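# Methods

## Model and procedure

The package measures disease similarity through the transcriptional
response of functional modules — gene sets standing in for protein
complexes and pathways, supplied as a GMT catalog (the package consumes
the catalog; it does not mine modules from an interaction network).

**Normalization.** Expression values are z-scored per sample column
(mean 0, sd 1 with the n−1 denominator). Per-sample scaling makes
values comparable across arrays and platforms and makes the whole
pipeline invariant to per-sample location/scale; note it also removes
any per-sample constant exactly, which is why batch structure has to be
gene-specific to matter (see the generator below).

**Gene response score.** `S_ik` is the t-statistic contrasting disease
against control samples of disease *k* for gene *i*. For a single study
it is the pooled-variance two-sample t — deliberately pooled rather than
Welch, so it is *identically* the t of the disease coefficient β₁ in the
regression `Y = β₀ + β₁·X`. With several studies the model gains
experiment indicators, `Y = β₀ + β₁·X + Σ γ_k·I_k` (reference-cell
coding, first study absorbed into the intercept; any full-rank coding
gives the same β₁ t), and `S_ik` is the t of β₁ with N − p residual
degrees of freedom. This fixed-effects combination removes additive
per-study offsets exactly and is more aggressive than a random-effects
meta-analysis, which is the intent: between-experiment level differences
are nuisance, not signal. Genes present in only a subset of a disease's
studies are scored on that subset; genes with zero residual variance or
a rank-deficient design are reported missing (NaN) rather than ±∞ so
module means stay finite.

**Module response.** `M_ik` is the arithmetic mean of `S_ik` over the
module's scored genes; the control-response matrix is the analogous mean
of per-gene control z-scores. Modules with fewer than `min_genes`
(default 2) scored genes are missing — a mean over at least two genes
avoids singleton noise while keeping coverage; genes in several modules
contribute to each with equal weight.

**Similarity.** For diseases (a, b) the partial Spearman correlation of
`M·a` and `M·b` conditions simultaneously on both control-response
columns `C·a` and `C·b`, restricted to modules observed in all four
vectors (pairwise deletion per disease pair, preserving coverage). All
four restricted vectors are ranked once with average ties; every
intermediate correlation is Pearson on those ranks; the one-variable
recursion
`r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`
is applied twice. On ranks this equals the correlation of least-squares
residuals after regressing the ranked vectors on the ranked conditioning
set — the equivalence is enforced to 1e-8 in the tests and serves as the
module's oracle. Degenerate cases: a pair is undefined below 4 shared
modules; an intermediate denominator within 1e-12 of zero yields an
undefined (NaN) result; if the two conditioning vectors are
rank-collinear the computation falls back to conditioning on one of them
(which is what the residual-regression definition does for a collinear
design).

**Significance.** The null rewires the gene–module bipartite graph by
double-edge swaps (10×|edges| attempts; a swap is rejected if it would
duplicate a membership), exactly preserving module sizes and per-gene
module counts, and independently permutes disease/control labels within
each study (group sizes preserved, and within-study so the experiment
indicators keep their meaning). MRS, control responses and all pairwise
partial correlations are recomputed per replicate; R = 100 replicates
are pooled across replicates *and* pairs into a single background
distribution — at R = 100 a per-pair null cannot resolve p = 0.01, so
pooling is the only reading consistent with that threshold. Empirical
p-values are one-sided on positive correlation with the add-one rule,
p = (1 + #{null ≥ obs})/(1 + #null), so p is never 0. The empirical FDR
at a cutoff is the mean per-replicate count of null statistics passing
the cutoff divided by the observed discoveries, in percent.

**Clustering and export.** Average-linkage agglomeration at distance
1 − ρ; disease labels are sorted so equal-height merges break ties
lexicographically; pairs with undefined ρ are imputed at ρ = 0 for the
tree only (logged, never used for significance). The tree is exported
as Newick, the significant-pair network as SIF plus an edge-attribute
table.

**Signature.** A module is in the common disease-state signature when
(1) the median of its |MRS| across diseases (missing entries ignored)
beats a null built by catalog randomization *only* — label shuffling is
deliberately omitted here, since the test asks whether the observed
gene scores concentrate in this particular gene set — at empirical
p < `p_cut` (default 0.01), and (2) |MRS| exceeds `mrs_threshold`
(default 1.5, strict inequality, read literally from its definition) in
at least `min_diseases` diseases (default 20). The two filter stages
commute; both thresholds are exposed as parameters rather than
re-derived from a null, which keeps the selection reproducible.

**Enrichment.** Overlap tests are upper-tail hypergeometric
probabilities computed by a log-sum-exp over gammaln-based log-pmfs, so
tails near the double-precision floor (~1e-300) remain finite and
monotone. The default tail is inclusive, P(X ≥ k) ("the observed
overlap or more"); a `strict` flag gives P(X > k), which is the
convention that reproduces the published per-pair drug-overlap and
druggable-family values and is used when recomputing those statistics.
The one-sided Fisher's exact test is implemented as the identical
hypergeometric tail on the fixed-margin table and is cross-checked
against `scipy.stats.fisher_exact` in the tests. Universe sizes default
to the knowledge base itself (distinct disease-associated genes; total
drugs) and can be overridden. Genes without a family annotation are
never druggable (conservative). The diseases-treated comparison uses a
one-sided permutation test on the mean (resampling signature-sized
target sets), since no analytic test is implied by the statistic.

## Synthetic-data generator

The generator emulates the statistical structure of a public-repository
compendium: per disease, `studies_per_disease` experiments with
`samples_per_group` disease and control samples each; baseline
expression i.i.d. Gaussian(0, `noise_sd`); per-gene, per-study batch
offsets Gaussian(0, `experiment_offset_sd`) shared by all samples of the
study (gene-specific by design — a scalar per-study offset would be
removed exactly by per-sample z-scoring and would leave the experiment
indicators nothing to do); module-level dysregulation adding
±`effect_size`·`noise_sd` to disease samples of member genes, signs half
up / half down so both MRS tails are exercised, with effects summed for
genes in several dysregulated modules and an optional per-gene dropout
(default off). Planted disease pairs share dysregulated modules at a
stated Jaccard overlap (shared block of size s with s/(2m−s) = J, same
signs in both diseases, remaining modules disjoint); signature modules
get one global sign and are planted in a stated fraction of diseases.
The knowledge base plants exact gene and drug intersections for
designated pairs. All randomness flows from one seed through named
substreams (catalog / compendium / knowledge base), so each artifact is
independently reproducible.

Defaults (500 genes, 100 modules of 4–10 genes, 10 diseases, 2 studies
of 4+4 samples, effect 3σ, unit noise, unit batch sd, 10 dysregulated
modules per disease) are desk-scale stand-ins for a compendium-scale
analysis; the calibration and recovery studies in
`moduledisease.benchmarks` use 10–25 diseases, 200 modules and 100 null
replicates, sizes chosen so planted effects are comfortably detectable
while a full benchmark run stays in the minutes range.

What the generator does *not* emulate: probe-level microarray artifacts,
platform mapping, intensity-dependent variance, correlated baseline
expression between genes, or time-series structure. Passing recovery
tests therefore demonstrate the pipeline's correctness and calibration
under the stated noise model, not performance on real arrays, where
gene–gene correlation inflates the variance of module means and
similarity estimates.

## Numerical and design choices

- z-scoring uses the sample (n−1) standard deviation, consistent with
  the downstream t-statistics.
- Zero-variance samples raise an error naming the sample; zero-variance
  genes become missing scores with a warning.
- Empirical p-values can never be 0 (add-one rule); significance of
  disease similarity is one-sided positive, matching the
  similarity-network interpretation of edges.
- The benchmark signature study uses 25 diseases with the
  differential-expression count required in more than half of them
  (13), mirroring the "dysregulated in at least half of the diseases"
  reading at the benchmark's disease count; the package default for
  `min_diseases` remains 20.
- Catalog rewiring attempts 10×|edges| swaps (configurable constant), a
  conventional mixing heuristic for degree-preserving randomization.
- Pipeline stage seeds are derived from the run seed through named
  spawn keys, so adding a stage does not perturb earlier stages'
  randomness; the output manifest records SHA-256 checksums of every
  file for byte-level reproducibility checks.

## Known limitations

- The fixed-effects experiment indicators assume additive per-gene batch
  effects; multiplicative or interaction batch structure is not modeled.
- Pooled-null empirical p-values are exchangeable across pairs only if
  pair-specific null scales are comparable; strongly unbalanced module
  coverage between pairs would argue for a per-pair null at much larger
  R.
- The hypergeometric drug-overlap universe treats drugs as exchangeable;
  chemically similar drugs violate that independence and bias the
  overlap p-values optimistically.
- Average-linkage trees are not guaranteed monotone for arbitrary
  dissimilarities; with 1 − ρ distances in [0, 2] inversions are rare
  but the Newick export clamps no heights — tests assert monotonicity
  only on the data regimes the package targets.
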