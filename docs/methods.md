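# Methods

## Overview

`dcgscan` tests, gene by gene, whether the correlation between DNA
methylation and gene expression differs between tumor and normal
samples, and characterizes the called genes. The pipeline assumes two
aligned matrices per cohort — normalized log expression (genes ×
samples) and methylation beta values (CpGs × samples) — plus a CpG
annotation mapping each probe to a gene, a genomic position and the
closest TSS, and a sample→group table. Group sizes may be unequal
(e.g. 8 normal vs 57 tumor) and each group needs at least 4 samples for
a defined correlation.

## Preprocessing

Beta values are mapped to M values, `M = log2(beta / (1 − beta))`, with
betas clamped to `[eps, 1 − eps]` (default `eps = 1e-6`) so boundary
values stay finite. Statistics are computed on the M scale, where
values are approximately Gaussian; robust CVs are computed on the beta
scale. Each dataset's M matrix is quantile-normalized across all of its
samples jointly — tumor and normal together, so group-specific
distributional artifacts are not introduced; a `separate_groups` flag
normalizes within group instead. Ties receive the mean of the reference
quantiles they span. CpGs are averaged per gene (unweighted mean;
probes mapping to several genes are counted in each, with a warning),
and analyses are restricted to genes with both expression and
methylation measures; with several cohorts, to the sorted intersection
of their gene sets. The robust coefficient of variation is
`100 · IQR / median` with linear-interpolation quartiles (the numpy
default; the convention matters for small n and is stated here because
there are several).

## Correlation engine

Within each group independently, Spearman (default) or Pearson
correlations are computed per gene (gene-averaged methylation vs
expression; the 27K-style unit) and per CpG (CpG methylation vs its
gene's expression; the 450K-style unit). Spearman is computed as
Pearson on average ranks. Correlations are Fisher-transformed,
`z = atanh(r)`, after clamping `|r|` at 0.999999 so perfect sample
correlations stay finite. Genes or CpGs that are constant within a
group have no defined correlation and are excluded with a logged count.

## Genome-wide comparisons

Signed correlations are compared across the genome with a paired
Wilcoxon signed-rank test on per-gene (normal − tumor) differences:
exact null distribution up to 25 non-zero differences, normal
approximation with continuity correction beyond, zero differences
dropped. The location estimate is the Hodges–Lehmann pseudomedian of
differences with a 95% CI from Walsh-average order statistics; for
large inputs the order statistics are found by bisection on a
vectorized counting function rather than materializing all n(n+1)/2
Walsh averages.

Absolute correlations shrink toward zero at different rates under
unequal group sizes, so the absolute-mode comparison subsamples the
larger group *without replacement* to the smaller group's size,
recomputes that group's per-gene correlations, runs the paired test on
|r| pairs, and repeats (default 1000 replicates); the reported p-value
and estimate are the means across replicates (the median p is also
emitted — mean-of-p is conservative and nonstandard, but it is the
convention this pipeline implements deliberately). Data are *not*
re-normalized per subsample: normalization is a cohort-level operation
and re-running it per replicate would conflate normalization variance
with sampling variance. Equal-sized groups bypass the machinery and
use a single direct test, bit-identical to the signed-mode code path.
Across cohorts, p-values are adjusted with Benjamini–Hochberg.

## DCG calling

*Single-correlation mode* (sparse arrays): the Fisher z-test for two
correlations, `z = (z_t − z_n) / sqrt(1/(n_t−3) + 1/(n_n−3))`, gives a
two-sided and a one-tailed p per gene. The `1/(n−3)` variance is used
for both Pearson and Spearman z's; a `spearman_variance` flag switches
to the `1.06/(n−3)` variant.

*Stouffer mode* (dense arrays): each CpG contributes one-tailed
p-values for both directions ("correlation higher in cancer" and its
complement); each tail is combined across a gene's CpGs with the
unweighted Stouffer Z-score method, `Z = Σ Φ⁻¹(1 − p_i)/√k`. The
gene-level two-sided p is `min(1, 2 · min(tails))` — the paper trail
behind this construction is a pair of directional gene lists, and
doubling the smaller combined tail jointly controls the FDR over both
directions while reducing exactly to the single-correlation test when
k = 1 (the one-p Stouffer combination returns its input unchanged).
BH q-values and Bonferroni-adjusted p's are computed across genes; the
calling direction is the smaller tail.

Stouffer combination assumes independent CpG statistics. Spatial
autocorrelation of the per-CpG Δz along the gene would inflate the
gene-level Type I error, so a Mantel permutation test between the
pairwise genomic-distance matrix and the pairwise |Δz_i − Δz_j|
dissimilarity matrix is run per gene within three TSS-distance strata
(<200 bp, 200–1000 bp, >1000 bp; at least 3 CpGs), with BH correction
across genes per stratum. A pooled-per-stratum variant is available by
flag. The permutation p is `(1 + #{r_perm ≥ r_obs})/(1 + n_perm)`;
sampled relabelings exclude the identity, which is already accounted
for by the `+1`.

## TSS-distance regression

Per-CpG Fisher-z correlations are pooled across genes and regressed on
absolute TSS distance separately per group with a P-spline: a cubic
B-spline basis of dimension k = 20 with interior knots at distance
quantiles and a second-order difference penalty, the smoothing
parameter chosen by minimizing GCV `n·RSS/(n − tr(A))²` over a
log-spaced grid (10⁻⁴…10⁸, 49 points). This 1-D penalized spline
stands in for a thin-plate basis; for a single covariate the fits are
practically equivalent. Pointwise 95% bands come from the Bayesian
posterior covariance `σ²(XᵀX + λS)⁻¹`. The reported `edf` excludes the
intercept (a fully penalized fit — the penalty's linear null space —
reports edf 1), matching the convention of mainstream GAM software.
`k` is reduced with a warning when the data have fewer distinct
distances than basis functions.

Basis adequacy: the k-index is
`var(diff(residuals ordered by distance)) / (2 · var(residuals))` — the
factor 2 makes the statistic ≈1 for exchangeable residuals, and a
remaining smooth trend pushes it below 1. Its p-value is the fraction
of residual-order shuffles with a k-index at or below the observed one
(20,000 shuffles in full runs, fewer in tests).

The promoter-proximal contrast splits CpGs at 5 kb absolute TSS
distance (configurable): a paired t-test on per-CpG `z_n − z_t` within
and outside the boundary (the same CpGs exist in both groups, so
pairing is the natural reading); the correlation ratio `z_n / z_t` per
CpG, compared between regions with a two-sample Wilcoxon rank-sum test
(CpGs with `|z_t| < 1e-8` excluded from ratios); and the fraction of
CpGs whose correlation sign flips between groups, per region.

## Summaries and enrichment

Per-feature group means, SDs (n−1) and robust CVs are tabulated, with
an optional promoter (<1 kb absolute TSS distance) vs non-promoter
stratification. Contrasts use the Wilcoxon signed-rank test for paired
features and the rank-sum test for disjoint sets, both with
Hodges–Lehmann estimates and CIs; covariate comparisons (GC content,
CpG count, expression level) remove called genes from the background
first. A diagnostic reports the Spearman association of −log10 gene
p-values with CpG counts per direction — a strong association would
mean the combination rewards coverage rather than signal.

Gene-set enrichment is an upper-tail hypergeometric test against a
user-supplied background, with the annotation intersected with the
background first. The genomic overlap test takes case/control-labeled
gene segments and a track (BED, 0-based half-open): the statistic is
case base pairs covered by the merged track (segment count by flag),
and the null permutes the case/control labels over the fixed segment
set, preserving the case count; `p = (1 + #{null ≥ obs})/(1 + n_mc)`
with at least 1000 Monte-Carlo samples recommended. Replicate tracks
are merged with Stouffer's method and BH correction is applied within
user-defined track batches (tracks from one source form one batch).

## Synthetic cohorts

The generator emulates paired array cohorts. Per gene, a latent
standardized expression vector u is drawn per group; each CpG's M value
is `mu_c + 1.5·(ρ·u + sqrt(1−ρ²)·v)` with v independent N(0,1), so the
population M–expression correlation is exactly ρ, and beta =
2^M/(2^M+1). Because the logistic map is monotone, Spearman
correlations are unaffected by the return to the beta scale, while
Pearson correlations on betas are attenuated — another reason the
pipeline analyzes M values. CpGs of one gene share only u, so two CpGs
have correlation ρ_i·ρ_j: independent when the target is 0 (the regime
used for null calibration), mildly dependent otherwise, which is
realistic and motivates the Mantel diagnostic.

The target ρ depends on group and absolute TSS distance; the defaults
(−0.4 within 2 kb rising smoothly to +0.15 beyond 5 kb in normal;
−0.45 to +0.15 in tumor) reproduce the canonical promoter-negative /
distal-positive pattern and are configuration, not claims about any
particular tissue. Planted DCGs split a configured correlation
difference `dcg_delta` (default 0.8) symmetrically: the shift direction
d = ±1 moves `ρ_n` by `−d·delta/2` and `ρ_t` by `+d·delta/2`;
infeasible targets (|ρ| ≥ 1) raise. Defaults emulate a 450K-style
breast cohort: 8 normal vs 57 tumor samples, 3–8 CpGs per gene with
TSS distances to 50 kb; `k27` mode switches to 1–2 CpGs per gene.
Expression baselines are Uniform(6, 12) log-intensity with unit-SD
noise; per-CpG M baselines are N(0, 2) with scale 1.5 — chosen once as
plausible array magnitudes. One `numpy` generator seeded from a single
integer drives all draws; identical seeds give bit-identical cohorts.

What the simulator does *not* model: batch effects, probe
cross-hybridization, detection failures, copy-number confounding, and
realistic genome geometry (genes are evenly spaced on toy
chromosomes). Passing tests therefore demonstrate statistical
correctness and calibration of the pipeline under clean assumptions,
not robustness to array artifacts.

## Verification and problem sizes

The test suite checks the statistical core against closed-form and
exhaustive-enumeration oracles (signed-rank at n=3 against all 2³ sign
patterns; rank-sum 3v3 against all 20 splits; Mantel at 4 CpGs against
all 24 relabelings; the overlap test at 3+3 segments against all 20
label assignments), against independent implementations (scipy
correlations, scikit-bio's Mantel statistic, R mgcv for the penalized
spline), and by Monte-Carlo calibration: the Fisher z-test's Type I
error at n=50/50 over 20,000 null draws, and the full Stouffer pipeline
on a 2000-gene null cohort (20+20 samples, 5 independent CpGs/gene),
where gene-level p-values are uniform (KS) and BH makes ~no
discoveries. Recovery is measured on 2000 genes with 10% planted DCGs
(Δρ = 0.8, 50/50 samples): sensitivity ≥ 0.8 and empirical FDR ≤ 0.10
at q < 0.05. The end-to-end run uses a 6000-gene, 8-vs-57 cohort with
100–200 subsampling replicates; full analyses would use the 1000
replicates and 20,000 adequacy shuffles cited above.

## Known limitations

- Mean-of-p aggregation in the subsampled absolute test is conservative;
  the median is reported alongside.
- The Stouffer gene p is exactly 2·min(tails); with dependent CpGs it
  can be anti-conservative, which the Mantel diagnostic flags but does
  not correct.
- The spline pools CpGs across genes; gene identity is not a grouping
  factor, so genes with many CpGs weigh more.
- The overlap test's bp statistic is one of several reasonable choices;
  segment-count is offered, but richer statistics (e.g. Jaccard) are not.
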