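# Methods

This note describes the statistical procedures `dgsea` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Problem setting

The package targets case-control transcriptome studies in which individual
transcripts show little or no significant differential expression, but
coordinated shifts of functionally related gene sets are detectable and
replicate across cohorts — the situation typical of whole-blood expression in
neurodegenerative disease. The questions it answers are: which gene sets are
directionally dysregulated; whether two independent analyses (two cohorts, or
blood versus brain) agree more than chance; and whether a co-expression
module's hub genes are preferentially dysregulated.

## Per-gene statistics (`diffstats`)

**Normalisation.** Median-of-ratios size factors: the per-gene reference is
the geometric mean across samples over genes with no zero count; a sample's
factor is the median of its count/reference ratios, renormalised so the
factors' geometric mean is 1 (making the library-size scale identifiable).

**Differential test.** A per-gene negative-binomial log-linear model with the
case/control (or manifest/premanifest) indicator plus age and gender
covariates and offset log size factor. The NB is parameterised as
variance = mu + alpha·mu² (alpha = dispersion). Dispersion is estimated per
gene by method of moments on the Poisson-fitted means, then refined by a
bounded profile-likelihood maximisation in log-alpha (bounds 1e-8 to 50) with
the means held fixed; the final fit is a fixed-alpha NB GLM and inference is
the Wald z for the contrast coefficient. This is deliberately plain — no
outlier rejection, no dispersion shrinkage across genes, no independent
filtering — because everything downstream needs only a well-calibrated
per-gene z; fully featured external results can be injected via
`import_stats`, which reconstructs directional p-values from effect sign and
two-sided p. Genes whose fit fails are excluded and listed with a reason,
never imputed.

**Directional p-values.** p_up and p_down are the continuous upper and lower
tails of the standard normal at z (t tails for the severity regression), so
p_up + p_down = 1 and p_two = 2·min(p_up, p_down) hold identically. All
p-values are floored at 1e-300 so the chi-square conversion stays finite.

**Severity regression.** Restricted to carriers with a recorded motor score
(TMS), the model is log2(count/size_factor + 1) ~ TMS + age + gender, fitted
by ordinary least squares for all genes simultaneously (the design matrix is
shared), with t-tail directional p-values. Covariate adjustment for age and
gender in this regression is a package choice; the pseudocount of 1 is
documented here because it sets the behaviour at zero counts. Whether
disease stage should enter categorically or ordinally is genuinely open; the
contrast is coded categorically.

## Directional enrichment (`enrichment`)

Each gene's weight in a given direction is the 1-df chi-square statistic
whose upper-tail probability equals its one-sided p-value
(`chisq_from_p = chi2.isf(p, 1)`); this maps p = 1 to weight 0 and is
strictly decreasing in p. Genes are ranked by weight descending with ties
broken by gene identifier ascending, which makes rankings — and therefore
every downstream p-value — bit-reproducible across platforms.

The enrichment score is the signed maximum deviation of the weighted
running sum: hits add w^exponent normalised by the set's total, misses
subtract 1/(N − |S|), so ES lies in [−1, 1]. The exponent defaults to 1
(weighting "by the statistic"); it is exposed in configuration because the
exact running-sum variant is an assumption, not a given. The leading edge
comprises the member genes at or before the running-sum maximum for
positive ES, and at or after the minimum for negative ES — for a negative
score those are the genes that drive the deficit.

**Null distribution.** Significance comes from permuting the gene-wide
statistics among gene labels, not from phenotype permutation. One shared
stream of label permutations serves every set in the collection, preserving
the inter-set correlation induced by overlapping memberships; this is what
licenses the overlap-excess test below. p = (#{permuted ES ≥ observed} + 1)
/ (R + 1), so p ≥ 1/(R+1) and zero p-values are impossible. Defaults:
R = 10,000 for flat runs, 1,000 inside nested procedures. Collections are
filtered to sets with 3–500 members after intersection with the universe
(bounds configurable; the module adapter lifts the ceiling because published
co-expression modules frequently exceed 500 genes).

**Multiple testing.** Storey q-values at fixed lambda = 0.5:
pi0 = min(1, max(#{p > λ}/((1−λ)m), 1/m)), followed by the pi0-scaled
Benjamini-Hochberg step-up with a cumulative minimum. The cited smoother
over a lambda grid is intentionally out of scope; fixing lambda keeps the
estimate deterministic and is accurate for the set sizes involved. Setting
pi0 = 1 reproduces plain BH exactly (cross-checked in tests against
statsmodels). Up- and down-direction q-values are computed separately,
because up- and downregulated findings are reported as separate lists.

## Cross-dataset statistics (`concordance`)

**Sign concordance.** A gene is "upregulated" iff its fold change is
strictly greater than 1 (log fold change > 0); boundary genes count as not
upregulated and their number is reported so boundary mass is visible. With
marginals a/n and b/n the null concordance probability is
p0 = (a/n)(b/n) + ((n−a)/n)((n−b)/n), equivalently
p0 − ½ = 2(a/n − ½)(b/n − ½). The observed concordant count is tested
against Binomial(n, p0) with an exact upper tail computed by log-space
summation (gammaln-based log pmf + logsumexp): at n in the tens of
thousands the tails of interest are far beyond normal-approximation
territory. p0 is additionally reported truncated (not rounded) to four
decimals, and the expected count under truncate-then-multiply, because
that is the printed-table convention the worked example follows.

**Replication counts.** For a fixed external gene list, the number of
members reaching p < alpha is tested against an exact Binomial(m, alpha)
upper tail.

**Overlap excess.** Given enrichment results for a reference dataset A and
per-gene statistics for a comparison dataset B over the same collection,
the observed statistic is the number of sets enriched (p < alpha, same
direction) in both. The null permutes B's gene-wide statistics among gene
labels with the shared stream. Re-running a full nested permutation test
inside every outer permutation would cost O(R²); instead each outer
permutation's per-set p-value is computed as the rank of its ES within
that set's R-permutation ES pool (ties counted as ≥). This is the standard
nested-permutation shortcut and yields the same null up to the ±1 p-value
convention. alpha ≥ 1 is treated as the degenerate "everything significant"
threshold, since permutation p-values can equal 1 exactly. The choice to
permute the comparison dataset while holding the reference fixed is a
design decision recorded in the output metadata; both orientations can be
run by swapping the arguments.

Because the overlap count is small and integer-valued, the null p-value is
discrete and conservative near 1; its calibration is therefore tested as
type-I-error validity at alpha (no anti-conservative inflation), not as
exact uniformity.

## Modules (`modules`)

The eigengene is the first right singular vector of the per-gene
standardised module submatrix, unit norm, sign-oriented so the mean member
correlation is nonnegative (the antisymmetric two-gene case yields mean
correlation zero and is documented as degenerate). kME is the Pearson
correlation of a gene with the eigengene; constant genes yield missing
values. Module discovery (soft thresholding, topological overlap, tree
cutting) is out of scope — modules arrive as definitions.

The kME-dysregulation test uses Spearman correlation between kME and
−log10 of the one-sided p in the direction of interest (both choices
exposed: pearson|spearman, transform on|off, since the original analysis
does not state them), with a seeded label-permutation p-value (one-sided
for positive correlation) rather than the t approximation, because bounded
p-value inputs are far from normal. When a module carries a reference
disease-status correlation, results are flagged same-direction /
opposite-direction / unoriented by comparing the tested direction with the
reference sign.

## Synthetic data (`simulate`)

Counts are drawn from the gamma-Poisson construction of the negative
binomial: count ~ Poisson(Gamma(1/alpha, alpha·m)) with
m = s_j · mu_g · 2^(beta_g·case_j + gamma_g·TMS_j). Defaults, chosen once
as the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_cases / n_controls | 112 / 22 | first cohort's carrier/control counts (74/27 for the second) |
| baseline log-mean | Normal(4, 1.2) (natural log) | median ≈ 55 counts, right-skewed like bulk RNA-Seq |
| dispersion alpha | Gamma(shape 2, rate 10) | mean 0.2, typical bulk over-dispersion |
| library-size log-SD | 0.25 | a few-fold depth variation, mean-centred in log space |
| TMS (carriers) | round half-normal, sigma 17 | mean ≈ 14, matching the first cohort's motor-score mean; controls 0 |
| effect_log2fc | 1.0 | the embedded-effect magnitude used in the recovery checks |

Set-level truth assigns up/down directions to a configured fraction of
sets; member genes inherit ±effect_log2fc (and ±severity_slope). When a
gene belongs to conflicting sets the first-assigned set wins and the
conflict is recorded — conflicts must be visible to tests, never silently
averaged. Gene identifiers are zero-padded ("G000001") so lexicographic
tie-breaks are deterministic. A second cohort can reuse a first cohort's
truth while redrawing baselines, dispersions and covariates, emulating two
cohorts that share biology but not samples.

The generator emulates: NB counts with gene-wise dispersion, library-size
variation, age/gender covariates, a severity covariate correlated with
case status, and directional set-level effects with controllable overlap.
It does **not** emulate: batch or surrogate-variable structure, GC or
length bias, globin carry-over, correlated expression within sets beyond
the shared mean shift, cell-type composition effects, or missing data.
Passing the null-calibration and recovery checks therefore demonstrates
the statistical machinery is correct and calibrated under the stated
generative model — not that any particular real dataset satisfies that
model.

The module fixture is a single latent factor z with per-gene loadings
λ_i: gene_i = λ_i·z + sqrt(1 − λ_i²)·noise, so each gene's theoretical kME
equals its loading.

## Numerical choices

- p-values floored at 1e-300 before chi-square conversion; chisq_from_p
  requires p ∈ (0, 1] and refuses zeros.
- Ranking ties broken by gene id ascending; permutation streams are
  `numpy.random.default_rng` seeded explicitly, with independent child
  streams (SeedSequence.spawn) for the two directions of a GSEA run.
- When the maximum positive and negative running-sum deviations tie in
  magnitude, the positive value is taken.
- Binomial tails by exact summation; empty upper tails return 1.
- OLS severity fits report t statistics with n − p degrees of freedom; an
  exactly-zero residual yields an infinite t, which the t tails map to the
  p floor.

## Problem sizes used in the checks

The test suite exercises the pipeline end-to-end at desk scale: null
calibration uses 150–1,600-gene cohorts over 20 seeds; set-level recovery
uses 100 sets of 10 genes over a 1,200-gene universe at 50 + 50 samples
(20 seeds), and the two-cohort overlap analysis 10 seeds at 200
permutations over a 4,800-gene universe. The overlap check needs the
larger universe for a scientific reason, not a computational one: the
gene-label permutation null is competitive, so if most of the universe
carries extreme-weight signal, random label assignments routinely capture
an extreme gene and every set's permutation p degrades. Keeping the
embedded-signal fraction transcriptome-realistic (about 2% here, versus
tens of thousands of measured transcripts in real data) preserves the
regime the test is meant to probe. These sizes were chosen so the full suite completes in
minutes while leaving the binomial Monte-Carlo margins stated in each
test; the machinery itself is size-independent and the permutation engine
is vectorised across sets (one shared label permutation costs O(M log M)
for total membership M).

## Known limitations

- The built-in differential test is not a DESeq2 replacement: no outlier
  handling, no shrinkage, no independent filtering. Use `import_stats` for
  externally computed tables when those features matter.
- Wald z calibration degrades for very small groups or very low counts;
  the null-calibration tests document the regime (tens of samples,
  moderate counts) where it is accurate.
- Fixed-lambda pi0 estimation is slightly conservative when the p-value
  distribution near 1 is irregular (e.g. heavily discrete permutation p).
- The overlap-excess null conditions on the reference dataset's observed
  significant sets; it does not model uncertainty in the reference
  analysis.
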