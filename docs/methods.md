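# Methods

This note documents the models, estimators and numerical choices behind
`coreinflam`, the assumptions they rest on, and what the synthetic-data
validation does and does not establish.

## Cross-species integration

All composite cross-species computations run on high-confidence one-to-one
ortholog pairs; the merged matrix is keyed by the species-A symbol. The
orthology table is a plain TSV (`gene_a_id, gene_a_symbol, gene_b_id,
gene_b_symbol, homology_class, high_confidence`) so the pipeline is
decoupled from any particular ortholog-database release. One-to-many and
many-to-many relations participate only in the expression-profile
classifier, where each mapped pair is tested independently and the BH
family is all tested pairs.

Normalization: log2(CPM + 0.5) with library sizes optionally TMM-scaled,
or log2(TPM + 1) when gene lengths are available. TMM follows the trimmed
mean-of-M-values recipe: reference sample by upper-quartile closeness to
the mean upper quartile, double trimming (30% of M, 5% of A), inverse
approximate-variance weights, factors rescaled to geometric mean 1. Note
that exact invariance to rescaling one library is impossible with
precision weights — the weights (n−y)/(n·y) depend on depth — so the
invariance holds only to ~1%, as in the standard implementation.

## Five-category expression-profile classifier

Candidate pairs are the union of lineage-specific genes of either species
mapped through any high-confidence relation, plus unmappable
lineage-specific genes. Each mapped pair is tested with a random-intercept
LMM, log2(TPM+1) ~ species + (1|study) against the null without species
(ML, not REML, since the models differ in fixed effects), BH over all
tested pairs. "High" expression means above the 95th percentile of the
candidate pool's per-species mean (computed per species by default; a
joint-pool switch exists because the underlying convention is ambiguous).
A pair diverges when padj < 0.05 and |β| ≥ 1; the sign of β decides which
species is the high one. Unmappable high genes fall into the no-ortholog
categories.

## Lineage markers

One-vs-rest DE per lineage is ordinary least squares on
[intercept, is_target] with empirical-Bayes variance moderation: a scaled
inverse-χ² prior (d₀, s₀²) is moment-matched to the log residual variances
via digamma/trigamma (Newton inversion of the trigamma function), the
posterior variance is the df-weighted blend, and the moderated t carries
d + d₀ degrees of freedom. F = t² for the single two-group contrast, which
is what markers are ranked by; up to 200 genes per lineage at padj ≤ 0.05
and log2FC > 0, ties broken by smaller padj then gene id. An optional
mean-variance-trend weighting stage is deliberately **not** the default:
unweighted OLS keeps the reference implementation simple and exactly
testable, at a small fidelity cost to the precision-weighted original.

PCA is a plain SVD of the feature submatrix after per-species
mean-centering; sample-sample Pearson matrices are clustered with average
linkage on 1 − r (linkage choice was open; average is the common default
for correlation distances).

## Per-study NB differential expression

The engine is a reference Wald test, deliberately simple and pluggable
(precomputed DE tables with columns `log2fc, se, stat, p, padj, base_mean,
tested` can be fed to every downstream stage):

* **Size factors**: median-of-ratios over genes positive in all samples,
  falling back to library sizes with a warning.
* **Dispersions**: method-of-moments on normalized counts using the pooled
  *within-group* variance (so a true condition effect does not inflate α),
  clipped to [1e-8, 10]; a parametric trend α(μ) = a₀ + a₁/μ is fitted by
  least squares (median fallback); the final dispersion is the
  equal-weight geometric blend of gene estimate and trend.
* **GLM**: log μ = log s_j + β₀ + β₁·x, fitted by IRLS vectorized across
  genes (each iteration is a closed-form 2×2 weighted solve), damped for
  stability, non-converged genes flagged untested.
* **Inference**: t reference with 2(n−2) df. The blend of the per-gene
  dispersion (n−2 df) with the trend makes the plug-in variance worth
  roughly twice the per-gene df; a plain normal tail is anti-conservative
  at n = 8 (null FPR ≈ 0.075 at nominal 0.05), while t with 2(n−2) df sits
  at 0.047–0.051 across null simulations.
* **LFC shrinkage** (optional, default on, flagged in the output): ridge
  with a normal prior whose sd matches the 99th percentile of the raw
  |log2FC|. On a mostly-null genome a central quantile would collapse real
  fold changes; the upper tail tracks the effect-size scale.
* **Count outliers**: a gene is masked when its worst squared Pearson
  residual exceeds 10× the median worst-residual across genes. Comparing
  extremes to the typical extreme keeps the flag rate at the rare-outlier
  level expected of the Cook's-distance machinery this replaces.
* **Independent filtering**: over a grid of base-mean quantiles, discovery
  counts (padj ≤ 0.05 after re-BH) are lowess-smoothed; the threshold is
  the smallest quantile within one residual SD of the smoothed maximum,
  and no filtering happens unless the smoothed gain over the unfiltered
  count exceeds max(1, residual SD). The literal "argmax discoveries" rule
  is unstable when discoveries are few and, combined with the ≥80%
  coverage filter, silently deletes true program genes.

## Fisher meta-analysis and program extraction

Genes must be tested in ⌈f·n⌉ of the n units (f = 0.8; a unit is a study
by default, a comparison by switch). Per gene, X = −2·Σ ln pᵢ over the
non-missing comparisons with p the *within-study BH-adjusted* values — a
statistically conservative choice kept for fidelity, with a raw-p switch —
and the combined p is the χ²(2k) survival with k varying per gene
(standard Fisher treatment of missingness). Zero p-values are clipped at
1e-300 with a warning. After BH across genes, the rank-R cutoff (R = 500)
is applied with boundary ties included; a kneedle alternative reports the
elbow of the (rank, −log10 padj) curve by maximal absolute distance from
the endpoint chord. The selection splits by the unweighted arithmetic mean
log2FC over contributing comparisons: m̄ ≥ 0.5 is the core (up) program,
m̄ ≤ −0.5 the down set; at θ = 0 exactly-zero means belong to neither. The
realized padj threshold is recorded in the manifest rather than treated as
a constant of the method, because it is data-dependent.

## Replicability and enrichment

**π1.** π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95; a natural cubic
smoothing spline (Green–Silverman form; penalty chosen by bisection so the
smoother trace equals 3 effective df) is read off at λ = 0.95 and clamped
to [0,1]; π1 = 1 − π0. The truncated-p variant rescales p′ = p/trunc
first, for p-value sets preselected below a cutoff. Caveat: on mixtures
whose alternative density still has mass above λ = 0.95 (e.g.
Beta(0.15, 1)), the estimand itself is biased toward π0 — for
π0 = 0.3 the plateau is π1 = 0.593, not 0.7 — and no implementation of
this estimator can do better; tests assert recovery of the closed-form
plateau.

**Pairwise replicability**: genes significant in unit i (padj ≤ 0.05)
contribute their raw p in unit j; π1 with truncation 1; entries with fewer
than 100 shared genes are left missing.

**Preranked GSEA**: running sum with hit increments |r|^w / Σ|r|^w
(w = 1) and miss decrements 1/(N−N_h); ES is the signed extremum,
candidates evaluated just before and after every hit. The null is
gene-label permutation (random same-size sets, n_perm = 1000 by default) —
matching preranked usage, not sample permutation; NES divides by the mean
|ES| of sign-matched permutations and the nominal p adds one to numerator
and denominator.

## Expression-matched backgrounds

Equal-frequency binning (B = 25) on the rank of pooled mean expression,
ties broken by stable gene-id order. Matched sampling reproduces the
target's bin profile exactly, without replacement within bins (with
replacement only when a bin is exhausted, with a warning). Module scores
are mean(program) − mean(pooled controls; 50 per program gene, program
genes excluded from control pools) per cell; gene means are pooled over
all cells before binning. Quantile capping at the 5th/95th percentiles is
a display field; the raw score is retained. The condition test delegates
to the LMM engine with sample (and optionally organ) random intercepts,
one model per control-vs-condition contrast.

**Wallenius overrepresentation**: the probability weighting function is an
isotonic regression of the DE indicator on the bias rank (expression),
clipped to (1e-4, 1−1e-4); the odds w is the ratio of mean PWF inside vs
outside the category. The pmf uses the single-integral representation
after the substitution t = u^D (which turns the integrand into a
Beta-like kernel) with explicit quadrature breakpoints within 1/D of
u = 1, renormalized to sum 1 ± 1e-8. This stays accurate in deep tails
where the generic scipy implementation loses precision; a moment-matched
normal approximation is the flagged fallback. An empirical check redraws
the category 1000 times with matched expression and reports the observed
percentile.

**Accessibility bootstrap**: s_obs counts program genes labeled
"increase" ("both" counts toward increase by default, switchable);
n_boot = 1000 matched sets give μ_b, σ_b; the two-sided p is the normal
tail of z = (s_obs − μ_b)/σ_b. The parametric tail is the point of the
studentized form — reported p-values far below 1/n_boot are only possible
that way; the Monte-Carlo percentile is the fallback when σ_b = 0.

**One-factor LMM**: profiled maximum likelihood — for a fixed variance
ratio θ = σ_b²/σ_e², GLS and σ_e² are closed-form via per-group Woodbury
sums; the 1-D profile is optimized on log θ with the θ = 0 boundary always
evaluated as a candidate. This is ~100× faster than a generic mixed-model
fitter, exactly deterministic, and well-behaved at the boundary, which the
null-calibration tests (hundreds of fits) require. The crossed
two-intercept case (sample + organ) delegates to statsmodels variance
components. LRT p-values use χ² with df = added fixed-effect columns.

## Synthetic data: what it emulates, and what a green test establishes

`gen_cross_species_studies` emulates the published compendium's shape:
11 studies (7 + 4 across two species), 10,000 genes, 4 samples per group,
counts NB(μ, α) with α ~ logNormal(ln 0.1, 0.5), a planted program of
150 up + 40 down genes with per-study log2FC ~ N(±1, 0.3) present in every
inflamed comparison, 50 study-specific DE genes per study, per-study batch
shifts (sd 0.3, chosen as a typical between-lab log2 offset), baseline
log2-abundance ~ N(5, 2) (a realistic bulk dynamic range), library sizes
uniform on 3–8 million (the compendium's median depth scale), and ortholog
baselines sharing a variance fraction of 0.8 across species (so the
expected cross-species correlation of baselines is 0.8). The single-cell
generator is log-normal with per-sample intercepts, an additive condition
shift δ on program genes and optional dropout; dropout attenuates any
planted shift by construction, so shift-recovery checks run at dropout 0.

What green tests establish: the estimators are calibrated under their
nulls, recover planted effects at the stated scale, and match closed-form
or brute-force oracles. What they do not establish: robustness to
phenomena the generators omit — unbalanced designs, confounded batches,
ambient contamination and doublets in single-cell data, count-level batch
interactions, or orthology errors. The study random intercept absorbs
additive batch effects but is no substitute for count-level batch
correction when batch and condition are confounded.

## Known limitations

* The NB engine is a reference implementation: no Bayesian LFC posterior,
  no Cook's distance, one covariate (condition) only.
* Fisher combination of *adjusted* p-values is conservative and non-uniform
  under the null; the raw-p switch exists and the choice is logged.
* The rank-cutoff tie rule ("include all boundary ties") can select far
  more than R genes when the padj distribution is heavily tied — in that
  regime the fold-change threshold does the real work, which matches how
  the selection behaves on weak data.
* π1 inherits the estimand bias described above for alternatives with
  appreciable mass near 1.
* The crossed-random-effects path depends on a generic optimizer and can
  be slow for large cell counts; the one-factor path does not.
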