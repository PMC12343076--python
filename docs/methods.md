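# Methods

## The statistical setting

Nested single-cell data arise from two-stage sampling: biological samples
are drawn first, then many cells are profiled per sample. For gene k the
package models expression as

    Y_cijk = mu_ck + b_cik + eps_cijk,
    b_cik ~ N(0, sigma_b^2),   eps_cijk ~ N(0, nu_eps^2),

with condition c, sample i, cell j. The intraclass correlation
rho = sigma_b^2/(sigma_b^2 + nu_eps^2) is the fraction of variance
attributable to between-sample heterogeneity; two cells of a sample are
correlated with exactly this rho. The `pseudoreplication` module provides
the closed forms: total variance, the variance of the difference-in-means
estimator (2/(Nn)) · Var[Y] · (1 + (n−1)rho), the inflation multiplier
1 + (n−1)rho, and the degrees-of-freedom pair (2Nn−2 naive vs 2N−2
correct). These are exact identities, not estimates.

`empirical_icc` estimates rho from data as a per-gene one-way ANOVA ICC(1)
with samples as groups on log1p-CPM values, with the n0 correction for
unequal group sizes; the pooled estimate is the median over genes. By
default the ANOVA is computed *within batches* (each gene centered per
batch; between-group degrees of freedom summed over batches): multiplicative
batch effects otherwise masquerade as sample-level correlation and, with
atlas-scale batch effects, dominate the estimate entirely (pooled ICC ≈ 0.22
even with no sample effect at all). `within_batch=False` restores the plain
one-way estimator. Samples with a single cell are excluded.

## The simulator

`simulate` produces gene × cell negative-binomial counts with known DE
ground truth:

1. **Base means** per gene ~ Gamma(shape 0.6, rate 0.3) — the published
   defaults of the splat simulation framework, which this generator
   re-implements at scenario level.
2. **DE genes**: a fixed fraction (default 5%) of genes; fold changes are
   log-normal, moment-matched so the natural-scale mean is 13.2 and sd 5.5
   (meanlog 2.5002, sdlog 0.4001; 5%/95% quantiles 6.31/23.53). Each DE
   gene is up- or down-regulated in condition 2 with probability 1/2 (down
   = reciprocal factor); the stated moments parameterize magnitudes only.
3. **Sample effects**: per sample × gene multiplicative factors
   exp(N(0, sd)) with sd = 0.35 by default. This value was calibrated once
   so the pooled empirical ICC on negative-control data is ≈ 0.05 — the
   same order as the worked pseudoreplication example — and then frozen.
4. **Batch effects**: per batch × gene factors with log-normal magnitude —
   (location, scale) defaults (0.05, 0.1), (0.8, 0.1), (1.45, 0.05) for the
   three atlas batches — and random direction (factor vs reciprocal) per
   gene, as in splat. The three magnitude distributions barely overlap, so
   batches are clearly separated.
5. **Library sizes**: per-cell log-normal factors scaled to mean one, so
   gene-sample means keep their scale; the default scale 0.2 gives ±20%
   depth variation.
6. **Counts**: gamma-Poisson with Var = mu + bcv²·mu², bcv = 0.1. No extra
   zero inflation — NB sampling of low means already yields realistic
   sparsity, and zero-inflated models are no longer considered a better
   description of UMI data.

Scenario presets: `dataset` (1 batch, 2 × 5 samples × 250 cells), `atlas`
(3 batches × 5 samples, 3750 cells; 3/2 condition split per batch with the
majority alternating, so every batch contains both conditions and the
global split is 8 vs 7), `varying_cells` (dataset layout with
cells-per-sample ~ round(Gamma(0.8, 0.0035)), floored at 10 — mean ≈ 228,
sd ≈ 255), `unbalanced_atlas` (two batches, 9:1 and 1:9 condition splits,
250 cells/sample), and `negative_control` (atlas layout, no DE genes).
The DE-gene count is exactly round(de_fraction × n_genes); the same seed
reproduces the dataset bit for bit.

**What the generator does not emulate.** Cell types and mixtures, doublets,
trajectories, ambient RNA, per-gene variability of the sample effect
(one sd for all genes), and mean-variance trends in the dispersion. Passing
benchmarks here therefore demonstrates correctness of the methods under the
stated hierarchical NB model, not performance on any particular tissue.

## The three DE tests

**Pseudobulk permutation test.** Counts are summed per sample (mass
conserving) and CPM-normalized — summation is the standard pseudobulk
convention, and CPM removes depth differences that would otherwise
confound a difference of means. The statistic is Δ = mean(cond 1) −
mean(cond 2) per gene. The null is obtained by reshuffling sample-level
condition labels: all C(S, n1) distinct assignments are enumerated when
their number is at most `exhaustive_threshold` (then p = b/n with the
observed assignment included, so p ≥ 1/n automatically), otherwise n_perm
Monte-Carlo shuffles are drawn and p = max(b, 1)/n. The test is two-sided
(|Δ_perm| ≥ |Δ_obs|); comparisons use a numerical-noise tolerance of
1e−9 × the gene's value scale so exact ties (the observed assignment, its
mirror, constant genes) are never lost to BLAS summation-order rounding.

**Hierarchical bootstrap.** Per iteration and condition: for each batch
shared by both conditions, draw with replacement as many samples as that
batch × condition stratum contains, draw `cells_per_draw` (default 100)
cells with replacement from each drawn sample, then subsample each batch's
pool uniformly without replacement to the smallest pool size across
batches, so every batch contributes equally many cells; the per-gene mean
of the pooled draw is the condition's value m_c,t. After n iterations,
c1 = #{m_1 > m_2}, c2 = #{m_2 > m_1}; ties count toward neither;
p = max(min(c1, c2), 1)/n, and a gene with all ties (e.g. all-zero) gets
p = 1. Genes at the floor 1/n after the initial 10 000 iterations are
re-run at 100 000 and `n_resamples_used` records the final count. Batches
present in only one condition are excluded from both conditions' draws
with a warning. The p-value is reported as the smaller directional
exceedance count (not doubled); `two_sided_double=True` doubles it.
Cell values are CPM by default; `raw` and `log1p_cpm` are provided for
sensitivity analysis. On simulated atlas data this choice matters: raw
ranks better than CPM (CPM introduces compositional coupling between DE
and null genes), and log1p_cpm better still, because the floor-tied genes
are then ordered by log-scale effects. The CPM default is kept as the
principled general-purpose choice (library-size robustness), not the
best-scoring one.

**Cell-level t-test.** Welch's unequal-variance t-test between the cells
of the two conditions on log1p-CPM values, two-sided. Zero-variance genes
with equal means get p = 1; p-values are clipped into (0, 1]. This test
deliberately ignores the nesting and is included as the pseudoreplication
baseline: on negative-control data with ICC > 0 its FPR at alpha = 0.05 is
far above 0.05.

All three methods are deterministic given a seed. Results carry a
`rank_score` total order — ascending p, ties broken by descending
|effect|, then lexicographic gene id — used for PR curves and top-N
selection; BH adjustment is applied to all tested genes.

## Evaluation

AUPRC is step-wise average precision (sum of precision × Δrecall over the
ranked sweep; no interpolation, which would overestimate the area). The
random-ranking baseline equals the DE prevalence. Truth is restricted to
the genes that survive the 10% detection filter, mirroring the pipeline
order. Calibration curves report the observed FPR over 2000 equidistant
p-value cutoffs in (0, 1] on null data. On negative-control data the
condition labels must be *uniformly* re-assigned (`permute_condition_labels`)
for the permutation test to be exchangeable: the preset's balanced
3/2-per-batch labeling is systematically less batch-aligned than a random
relabeling and makes the test look conservative. Because all genes share
one label draw, single-run calibration curves fluctuate; the benchmark
averages the curve over 20 runs, after which it sits on the diagonal
(max deviation ≈ 0.018 below cutoff 0.15).

`split_dataset` partitions cells into subsets of at most 4000 cells with
at least 20 cells from every sample (shuffled round-robin dealing with a
per-sample starting offset; the subset count is reduced with a warning if
a small sample cannot serve every subset, and the input rejected if both
constraints cannot hold). Reproducibility across subsets is the Jaccard
index of top-N gene sets.

`run_benchmark` wires it together: per scenario and replicate, simulate
(seed derived from base seed, scenario and replicate index), filter, run
each method, and record AUPRC in a tidy table; a method failure is
recorded as missing and the run continues.

## Problem sizes and numerical choices

The shipped benchmark settings are 5 replicates of 1000-gene scenarios,
exhaustive permutation (the C(20,10) = 184 756 assignments of the
unbalanced atlas enumerate in seconds), and 1000 initial / 10 000
escalated bootstrap iterations; a 20-replicate run reproduces the same
means within ±0.02. The exact permutation null is preferred over
Monte-Carlo sampling wherever feasible: with 10 000 shuffles the p-value
floor 1/n is reached both by true DE genes and by strongly
batch-confounded null genes, and the ranking collapses onto the effect-size
tie-break; exhaustive enumeration resolves those ties (floor 1/184 756).
Bootstrap weight matrices are assembled sparsely and multiplied in blocks
of 2000 iterations to bound memory.

## Known limitations

* The simulator is a scenario-level re-implementation of the splat/splatPop
  family from published defaults, not a byte-level replica; absolute AUPRC
  values on simulated scenarios depend on generator details (notably the
  single shared sample-effect sd) and differ from what richer generators
  produce. Under this generator the balanced atlas is an easy ranking
  problem for pseudobulk and cell-level tests (AUPRC ≳ 0.9), while the
  CPM-based bootstrap ranks worse (≈ 0.55–0.69); method orderings observed
  on other generators need not transfer.
* The bootstrap p-value measures sign stability of the condition
  difference under resampling. Genes with any persistent bias — e.g. a
  condition represented by a single sample in a batch — hit the floor
  regardless of iteration count, which inflates its FPR on null data; this
  is a property of the method, reproduced faithfully.
* External DE methods (DESeq2, DREAM, MAST, scVI, distinct) are not
  implemented or wrapped; their result tables can be scored with
  `evaluate` if produced elsewhere.
* H5AD/loom ingestion is out of scope; I/O covers 10x-style MTX triples,
  dense CSV, and TSV tables.
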