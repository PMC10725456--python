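# Methods

This note documents the statistical model the package implements, the
defaults and why they hold their values, what the synthetic generators do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## 1. Map reconstruction from peak coordinates

Coordinate-based meta-analysis begins from an irreversible compression: each
study reports only the local maxima of its thresholded contrast map. The
reconstruction assumes the underlying effect field is smooth at roughly the
scale of typical fMRI effects, and recreates a per-study signed Hedges' g
map by spreading each peak's effect with an isotropic Gaussian kernel,
`w(d) = exp(−4 ln2 d²/FWHM²)`, FWHM **20 mm** (the value the seed-based
d mapping tradition uses as a balance between sensitivity and specificity of
the recreated maps). Contributions of overlapping kernels **sum** and the
combined magnitude is **capped at the largest contributing |g|**: summation
preserves the single-peak decay profile (a normalised mean would paint a
constant plateau over the whole support), the cap prevents many nearby
same-sign peaks from inflating the effect beyond anything actually reported,
and opposite-sign peaks partially cancel. Kernels are truncated at 2×FWHM,
where the weight is below 0.04 %. Peaks outside the mask snap to the nearest
in-mask voxel centre when that is ≤ 6 mm away and are otherwise skipped with
a warning. The variance map follows the g-to-variance formula applied to the
reconstructed voxel value, so variance is exact at peaks and interpolates
consistently elsewhere; a zero-peak study contributes an all-zero effect map
with variance 1/n₁ + 1/n₂.

Statistics arrive in three forms. Explicit t-values are used directly.
Z-scores and p-values convert to t by matching the upper-tail probability of
the t distribution with n₁+n₂−2 degrees of freedom; reported p-values are
treated as one-tailed in the direction of the reported contrast (the SDM
converter convention; a flag accepts two-tailed). Peaks printed only as sign
markers ("p" = patients > controls, "n" = reverse) are imputed at the
magnitude a t exactly at the study's own uncorrected voxel threshold would
give, defaulting to voxel p = 0.001 one-tailed when the study reported only
a corrected level — a deliberate middle-of-threshold-range stand-in that is
logged whenever used. Talairach coordinates convert with the Lancaster
tal2icbm affine (SPM flavour), pinned in code as the inverse of the
published icbm_spm2tal matrix; the transform is a single affine, applied
once, with the exact inverse available for round trips.

**Not implemented** (documented simplifications): the anisotropic,
tissue-correlation-weighted kernel of full AES-SDM, and its multiple
imputation of censored effect sizes.

## 2. Random-effects pooling and the SDM-Z null

Voxel-wise pooling is DerSimonian–Laird: moment estimate of the
between-study variance τ² truncated at zero, re-weighting by 1/(var+τ²).
The estimator is vectorised over voxels and verified against an independent
implementation (statsmodels) in the tests; a single study degenerates to its
own effect and sampling variance.

The pooled mean is not referenced against a parametric distribution —
after kernel reconstruction its null distribution at a voxel depends on
peak counts, group sizes and mask geometry. Instead, a **peak-relocation
permutation null** relocates every study's peaks to uniformly random
in-mask voxels (peak count and g values preserved), re-reconstructs and
re-pools. SDM-Z is the pooled mean standardised by the null's per-voxel
mean and sd; empirical p-values are mid-p tail proportions (ties counted
half), so a voxel never touched by any peak in data or null reports p = 0.5
rather than an artefactual extreme. Defaults: **n_perm = 50** for map
standardisation (the AES-SDM default; calibration tests use 200 so that
p < 0.005 is resolvable, since the smallest attainable p is 1/n_perm).
Significance uses the uncorrected triple threshold **voxel p < 0.005,
peak |Z| > 1, extent > 10 voxels** — strict inequalities — with
**26-connectivity** components split by the sign of the pooled effect.
The null relocates peaks independently and uniformly; real peaks are local
maxima and therefore mutually separated, an asymmetry the calibration test
shows is negligible at these problem sizes.

## 3. Validation battery

*Heterogeneity / bias.* Per significant cluster, the per-study effect is the
mean reconstructed g over member voxels (peak-voxel aggregation available
behind a flag); Cochran's Q with chi-square reference and Egger's regression
of g/se on 1/se (intercept t-test, k−2 df) plus funnel-plot data.

*Jackknife.* The full engine reruns k times leaving one dataset out; a
voxel's stability is the fraction of reruns in which it belonged to a
significant cluster, and the stable mask keeps fractions **≥ 0.8**
(inclusive, so 4-of-5 qualifies).

*Subgroups.* Full reruns on any predicate over dataset metadata, refused
unless **strictly more than 10** datasets qualify. The shipped roster yields
11 binary-FNC datasets (runs) and 3 Philips datasets (refused).

*Meta-regression.* Within the union of main-analysis cluster voxels only —
regions outside the main findings are excluded to limit Type I error —
weighted least squares of per-study effects on the centred covariate with
random-effects weights. The slope's p-value comes from **permuting the
covariate across studies** (default ≥ 2000 permutations; the add-one
estimator bounds the smallest p at 1/(n+1), so 2000 permutations are the
minimum that can reach the **p < 0.0005** gate); a parametric t-test is
available behind a flag and is conservative when the covariate itself drives
between-study heterogeneity, because that heterogeneity re-enters through
τ². Supported covariates: patient mean age, % male patients, PANSS
total/positive/negative, illness duration, smoothing FWHM, correlation
threshold.

## 4. Expression interface

The expression side is a samples × genes matrix with MNI coordinates per
sample, as produced by an abagen-style AHBA export; probe aggregation,
donor pooling and per-structure normalisation are upstream provenance and
are not re-implemented. Map sampling averages the statistic over in-mask
voxels whose centres lie within a **4-mm** sphere of the sample coordinate
(membership by voxel-centre distance; partial volumes are not weighted);
samples with empty spheres are dropped and listed, and both the drop list
and the retained count are reported so users can reconcile sample counts
with their upstream filtering. Both sides are z-scored with the
**population (n) denominator** — the choice is immaterial to PLS directions
and is stated for reproducibility of intermediate values.

## 5. PLS and the spatial surrogate null

PLS1 is fit by NIPALS with deflation; for a univariate response the weight
step is closed-form per component, so the decomposition is deterministic.
Explained-variance fractions partition var(y) exactly. Five components are
extracted by default (covering the range where meaningful map variance
lives at these sample sizes).

Component significance must respect the map's spatial autocorrelation: a
naive permutation null destroys it and overstates significance. Surrogates
are built BrainSMASH-style: random permutation of y, Gaussian-kernel
smoothing over the sample graph at bandwidths {0.1 … 0.9}×max distance,
then an affine variogram rescaling (regressing the empirical variogram on
the smoothed one; the intercept becomes white-noise "nugget" amplitude),
keeping the bandwidth with the smallest variogram SSE. The empirical
variogram uses 25 bins up to half the maximum pairwise distance. p per
component is the proportion of surrogates whose same-index component
explains at least as much variance (the literal count/n estimator; a
(count+1)/(n+1) flag exists, and a zero count is displayed as "< 1/n").
The selected component is the lowest-p significant one (ties → larger
explained variance), sign-fixed so its score correlates positively with y.
Same-index comparison (rather than best-null-component) is the implemented
reading; the alternative is a one-line change and is noted at the call
site. Default **1000 surrogates**; a minimum of 10 samples is enforced
because the variogram is unstable below that.

Bootstrap gene weights: **1000** row resamples with replacement, each refit
component sign-aligned to the original by the sign of its score's
covariance with the original score on the resampled rows (without
alignment, NIPALS sign indeterminacy would corrupt the SEs); Z = w/SE,
two-sided normal p, Bonferroni at 0.05/G; positive-Z significant genes form
PLS+, negative PLS−.

## 6. Enrichment

*GCEA.* Category score = mean loading of member genes, where a loading is
the Pearson correlation between the selected component's score and the
gene's expression. The null ensemble refits PLS on each SA-preserving
surrogate response and recomputes null loadings and null category scores;
p is the one-sided proportion of null scores ≥ the real score. The PLS−
context negates loadings so "enriched" means strongly negative loading, and
both directions are run. Categories are intersected with the expression
gene universe and size-filtered to **[10, 200]** (toolbox convention)
before testing; GO-format inputs (OBO + GAF) are supported with is_a
propagation, and plain GMT files are the primary path.

*pSI / CSEA.* Cell-type specificity follows the specificity-index idea:
for a target cell type, genes are ranked by their expression advantage over
each other cell type, and the specificity index is the mean rank across the
m comparisons. Its p-value is the exact lower tail of a mean of m uniform
ranks (Irwin–Hall distribution, with rank r mapped to the uniform midpoint
(r−0.5)/G) — an analytic null that makes the four tiers 0.05, 0.01, 1e-3,
1e-4 nested by construction. This is a self-contained specificity measure
in the spirit of the published pSI tool, not a reproduction of its
mouse-derived tables; real pSI marker lists can be supplied directly.
Enrichment of PLS gene sets against each (cell type × tier) marker list is
a one-sided Fisher exact test over the post-intersection gene universe
(background choice stated explicitly), BH-FDR corrected across all tests at
q < 0.05.

## 7. Synthetic data: what it emulates, and what it does not

The generators produce inputs with exactly the statistical structure the
analysis assumes, so every pipeline guarantee is testable offline.

*Studies.* Per study, region effects g ~ Normal(g_true, τ²) are painted as
Gaussian bumps (sd = radius/2) on the grid, plus stationary smooth Gaussian
noise (Gaussian-filtered white noise with periodic boundaries — zero-padded
filtering would leave a variance dip at the array edge and bias peak
locations away from the boundary, breaking exchangeability with the uniform
relocation null). The study's t-map thresholds at its one-tailed reporting
p, and in-mask local maxima of |t| (3×3×3 neighbourhood evaluated on the
full volume, again to avoid boundary pile-up) become the reported peaks with
their local t. An optional publication-bias switch redraws below-median-size
studies whose best peak is not positive. Defaults: a 40×48×40 grid at 4 mm
with an ellipsoidal mask (≈29k voxels), **12 studies** of 30–80 subjects
per arm, one region of radius 16 mm with **g_true = 0.8, τ = 0.1**, noise
sd 0.25 (g units) at a 12-mm length scale, reporting p = 0.001 — sizes
chosen so a full pipeline run takes about a minute on one CPU.

*Expression.* Sample coordinates are drawn from in-mask voxel centres;
every gene receives spatially autocorrelated noise drawn exactly from a
squared-exponential Gaussian process (Cholesky of the 15-mm-length-scale
covariance over the sample coordinates, unit sd); **30 driver genes** among
**600** add λ×(standardised target value) with **λ = 1.5**. The driver
fixture is deliberately a high-signal power construction — strong enough
that Bonferroni-corrected bootstrap selection recovers essentially all
drivers with correct signs — because its role is to verify recovery
machinery, not to estimate realistic effect sizes.

*Annotations.* One category is a random subset of the drivers (known
enriched truth); the rest are size-matched random draws whose overlap with
the driver set is hypergeometric by construction. Cell-type profiles are
lognormal with one cell type overexpressing the drivers six-fold.

*What passing these tests does not show:* anatomically realistic masks or
effect topographies, AHBA donor structure (six donors, hemispheric
asymmetries, probe-level noise), realistic gene–gene co-expression (noise
genes are independent fields), or the selection biases of real literatures
beyond the simple small-study suppression switch. Recovery rates on this
fixture are upper bounds on what identical settings would achieve on real
data.

## 8. Reduced problem sizes in tests

Calibration suites run at deliberately reduced scale chosen once: the
no-effect voxel-calibration uses a 12×14×12 grid at 8 mm with 12 studies,
200 replicates and 200 permutations each; the PLS/GCEA null uses 60 samples
× 80 genes with 50 surrogates per replicate and responses drawn from the
surrogate generator itself; recovery tests use a 24×28×24 grid at 6 mm with
120 samples × 200 genes. These sizes keep every Monte-Carlo standard error
small enough for 3-SE acceptance bands while the whole suite completes in a
few minutes.

## 9. Known limitations

- The relocation null and the kernel reconstruction are explicit, documented
  stand-ins for AES-SDM internals that are not published at implementation
  granularity (overlap handling, null generation, marker imputation).
- Empirical p-values are bounded below by 1/n_perm; users chasing small
  thresholds must raise the permutation counts accordingly.
- Meta-regression treats the covariate as fixed and exact; measurement error
  in study-level covariates is not modelled.
- The variogram surrogate generator matches the binned semivariogram, not
  the full spatial covariance; long-range structure beyond half the maximum
  pairwise distance is unconstrained.
- Cluster-level diagnostics aggregate by unweighted voxel means within
  clusters; very elongated clusters may mix heterogeneous sub-effects.
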