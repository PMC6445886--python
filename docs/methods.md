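# Methods

This note documents the statistical models implemented in `benchmeta`,
the conventions chosen where reported formulas are ambiguous or silent,
what the synthetic-data generators do and do not emulate, and the known
limitations.

## Models

**Fixed vs random effects.** Study *i* reports an effect θᵢ with
standard error seᵢ = sdᵢ/√nᵢ. The fixed-effect model assumes a single
true effect γ with θᵢ = γ + εᵢ, εᵢ ~ N(0, seᵢ²). The random-effects
model assumes study-specific true effects μᵢ ~ N(μ, τ²), so
θᵢ = μᵢ + εᵢ; τ² is the between-study (interstudy) variance. Pooling is
the weighted mean θ̂ = Σwᵢθᵢ/Σwᵢ with wᵢ = 1/seᵢ² (fixed),
1/(seᵢ² + τ²) (random), nᵢ (sample-size) or 1 (unweighted), and
se(θ̂) = 1/√Σwᵢ for the inverse-variance schemes. At τ² = 0 the random
model coincides with the fixed model; as τ² → ∞ it tends to the
unweighted mean.

**Effect measures.** Absolute (mean or mean difference), standardized
(Hedges' g with the correction factor 1 − 3/(4(nc + nr) − 9) and the
se form containing (nc + nr) − 3.94), normalized
((θr − θc)/θc, the percent difference) and ratio (θr/θc with
delta-method se). The pooled sd for difference measures is
√(((nc−1)sd_c² + (nr−1)sd_r²)/(nc + nr − 2)).

**Log10 transformation.** For skewed, nonnegative outcomes the forward
transform assumes lognormality: se(Θ) = √(log₁₀(cv² + 1)) with
cv = se/θ, and Θ = log₁₀θ − se(Θ)²/2. Back-transformation offers
geometric (10^Θ̂, asymmetric CI, approximates the median), naive and
Taylor-series forms (both 10^(Θ̂ + se²/2) with different se
approximations). The naive/Taylor se forms involve sd(Θ̂) and a 1/√n
factor: at the pooled level we take sd(Θ̂) equal to the supplied
standard error and n as the total pooled sample size; both conventions
are recorded in the returned object. Whether a per-study or pooled n is
the right convention is genuinely underdetermined; the choice only
rescales the naive/Taylor se, never the point estimate.

## τ² estimators

With Q = Σwᵢ(θᵢ − θ̂_FE)², wᵢ = 1/seᵢ², c = Σw − Σw²/Σw, N studies:

| method | estimate |
|---|---|
| DL | (Q − (N−1))/c |
| HS | (Q − N)/Σw |
| H (Hedges) | sample variance of θᵢ − mean(seᵢ²) |
| HM | Q² / ((2(N−1) + Q)·c) |
| SJ | weighted variance with vᵢ = seᵢ²/τ₀² + 1, τ₀² = Σ(θᵢ − θ̄)²/N |
| PM | iterative: τ² such that Q_gen(τ²) = N − 1 |

All are truncated at zero. The Hedges estimator is implemented in its
variance-component form (the sample variance of effects minus the mean
within-study variance); an inverse-variance reading of the same symbols
is dimensionally inconsistent and always truncates. PM is solved by
bisection on [0, 10·max(se²) + var(θ)] to |Q_gen − df| < 1e−8 (at most
200 iterations), deterministically; the bracket is widened if needed.

## Heterogeneity statistics

Q is referred to χ²(N−1). H² = Q/df, truncated below at 1;
I² = (H² − 1)/H² · 100%. The H² interval exponentiates
ln H ± z·SE[ln H] with SE[ln H] = √((1/(2(df−1)))(1 − 1/(3df²))) and
squares the bounds (df ≥ 2; for df = 1 no interval is reported). The I²
interval maps the H² bounds through the same transform, flooring at 0.
H² is the preferred magnitude measure: unlike I² it does not saturate
near 100% under extreme heterogeneity, and unlike Q it does not grow
with the number of studies.

## Critical values and coverage

CIs use θ̂ ± v₁₋α/₂·se(θ̂) with v from the z distribution or the t
distribution at df = N − 1. `dist="auto"` uses t below 30 studies and z
otherwise (the t quantile converges to z as N grows). Coverage counts
study *i* as consistent with the pooled estimate iff
|θ̂ − θᵢ| ≤ v·se(θ̂) + v·se(θᵢ); values well below 1 − α indicate
excess heterogeneity or a mis-chosen model.

**Unweighted pooled se.** Only the inverse-variance schemes have a
formula-defined pooled se (1/√Σw); the sample-size scheme pools
study variances with weights (nᵢ − 1):
se(θ̂) = √(Σseᵢ²(nᵢ−1)/Σ(nᵢ−1)), with no additional division by a
function of total N (implemented exactly in this form). For the
unweighted scheme we use the empirical standard error of the mean,
sd(θᵢ)/√N. A single-study "pool" returns that study's own estimate with
a z-based CI.

## Sensitivity analyses

Baujat coordinates use squared numerators: xᵢ = (θᵢ − θ̂_FE)²/seᵢ²
(so Σxᵢ = Q exactly) and yᵢ = (θ̂₋ᵢ − θ̂_FE)²/se(θ̂₋ᵢ)², with the
leave-one-out estimate and its se computed under fixed effects — the
same anchor as the x axis. Cumulative exclusion removes, at each step,
the study whose removal maximally reduces Q (ties broken toward the
lowest index, logged), stopping when the Q-test p exceeds α (default
0.05) or two studies remain; the homogeneity threshold T_H is
100 · (removals to first homogeneity)/N. Q is always computed with
fixed-effect weights; the per-step pooled estimate honours the caller's
scheme.

## Subgroup analysis and meta-regression

Q_within sums per-group fixed-effect Q statistics;
Q_between = Q_total − Q_within (χ² with S − 1 and N − S df). The pooled
residual variance uses τ²_within = (ΣQⱼ − Σdfⱼ)/Σcⱼ with each cⱼ
computed within its group, and
R²_explained = (1 − τ²_within/τ²_total)·100, truncated to [0, 100] (the
raw value is retained for diagnostics — negative values arise from
sampling noise).

Meta-regression fits y = Xβ by weighted least squares; the random model
uses one-step method-of-moments τ² = (Q_residual − (N − p))/c_total from
the fixed-weight fit (no REML iteration, keeping the estimator within
the same moments family as the pooling layer). Coefficient covariance is
(XᵀWX)⁻¹ under the known-variance convention standard in meta-analysis,
with t-based CIs at df = N − p. The reported Q_residual is always
evaluated with fixed-effect weights at the fixed-weight coefficients so
the decomposition Q_model + Q_residual = Q_total is exact. Categorical
covariates are reference-cell dummy coded against the lexicographically
first level. An intercept-only regression reproduces the pooled weighted
mean exactly.

Intrastudy regression fits an ordinary least-squares slope per study
(≥ 2 distinct predictor levels; others are skipped with a warning) and
pools the slopes with the standard pooling rules, falling back to
unweighted pooling when slope standard errors are zero (two-point
studies). Comparing the pooled within-study slope with the meta-
regression coefficient in sign and magnitude guards against aggregation
bias: across-study relationships need not hold within studies.

Bonferroni adjustment for m pairwise subgroup contrasts replaces α with
α/m in the critical value; it is applied only when contrasts are
requested.

## Clustering

k-means on user-chosen study-level features (default: standardized
effect size, optionally log se), best of `n_init` starts, deterministic
given the seed; k is user-specified with an optional inertia-vs-k elbow
report. Dependence between cluster labels and a categorical covariate is
tested with plain Pearson χ² (no continuity correction); the test is
flagged invalid unless ≥ 80% of cells have expected counts ≥ 5.
Clustering is unweighted by design and always yields a partition, so
cluster structure is exploratory until supported by a covariate.

## Monte-Carlo error propagation

For curve data (xⱼ, θⱼ, sdⱼ, nⱼ), each iteration draws nⱼ
pseudo-observations from N(θⱼ, sdⱼ²) per level, averages them, and fits
the model by damped (Levenberg–Marquardt-type) nonlinear least squares
with model-specific starting values: closed-form for linear/quadratic,
log-linearization for exponential, (max θ, interpolated half-max x) for
Michaelis–Menten, the same plus unit slope for Hill. Residuals are
unweighted — the per-level averaging has already absorbed nⱼ. Failed
iterations are dropped and counted in `converged_fraction` rather than
imputed. One root seed spawns per-iteration substreams, so increasing M
extends the draw sequence without reshuffling earlier iterations.
Pseudo-observations are not truncated at zero by default (the sampling
model is plain normal); a `truncate_at_zero` option exists for
physically nonnegative quantities. Fit quality reports the R² of the
mean-parameter curve against the reported means and per-parameter
Shapiro–Wilk normality flags (≥ 10 draws); normal, unimodal parameter
distributions and high R² characterize reliable propagations. Note that
with many draws the Shapiro test detects even mild skew (e.g. in
EC50-type parameters), so a raised flag is a prompt to inspect the draw
distribution, not an automatic rejection.

## Figure digitization

Calibration fits an affine map from pixel space to (optionally
log10-transformed) data space by least squares over ≥ 3 non-collinear
reference points — three points rather than two per axis so slight axis
skew is absorbed; reference residuals above 2 px warn. Pixels use the
raster convention (origin top-left, y down); the affine map absorbs the
flip. Marked points and error-bar end points map through the
calibration, with 10^ back-transformation on log axes.

The validation harness replaces the human marking step with an
automatic detector: the renderer draws black circular markers of varying
size on an axis-free white canvas (placements rejection-sampled so
markers never overlap — one connected component per marker), records
ground-truth pixel and data coordinates, and supplies the axes-corner
reference pairs; the detector thresholds the raster and takes
darkness-weighted centroids of connected components, giving sub-pixel
precision from the antialiased edges. Detections are matched to truth
greedily by pixel distance within the marker radius + 3 px. Validation
regresses extracted on true values (slope, CI, R²), summarizes the
percent-error distribution, and regresses absolute error on marker
size. Because markers are symmetric and the centroid estimator is
unbiased, the pipeline shows unit slope and zero mean error; the harness
reproduces that statistical contract, not any particular human
click-jitter error range.

## Synthetic data

`SimulationSpec` defaults describe a well-behaved mid-size bench
meta-analysis: μ = 1, τ² = 0.25, N = 20 studies, per-study se uniform on
(0.1, 0.5), n uniform on 3–12 independent experiments. Reported sd and n
are mutually consistent (sd = se·√n) and independent by default — the
null of the sd²-vs-n diagnostic; `confound_sd_n=True` induces the
pathological sd² ∝ n coupling for testing that diagnostic. Lognormal
mode treats the normal draws as log10-scale values and exponentiates,
mapping sd to the raw scale by the delta method. Subgrouped and
regression generators shift the true mean by group offsets or a linear
term in a uniform covariate. Dose–response data place reported means on
the model curve with noise sd/√n.

What the generators do **not** emulate: publication bias and small-study
effects, non-normal within-study errors, correlated effect sizes from
shared labs or multi-arm studies, missing or misreported uncertainties
(beyond the sd²–n confounding switch), and unit heterogeneity across
studies. Passing tests therefore certify the estimators and procedures
under their stated assumptions, not robustness to every pathology of
real literatures.

## Problem sizes and numerical choices

Stochastic checks use sizes chosen for stable statistics at desk scale:
500 replicates for null-calibration rates (binomial sd ≈ 1%), 200
replicates for CI-coverage and τ²-recovery means, M = 400 Monte-Carlo
iterations for curve fitting, and 319-point renders for digitization
validation. Tolerances: decomposition identities to 1e−9 (exact algebra
up to float roundoff), PM bisection to 1e−8, noiseless model recovery to
1e−6 (optimizer tolerance). The weighted histogram defaults to
Freedman–Diaconis binning on the unweighted effects; any binning can be
forced. p-values are reported at machine precision with no multiplicity
correction outside the explicit Bonferroni layer.

## Limitations

No Knapp–Hartung adjustment and no likelihood-based τ² (REML, profile
likelihood); no trim-and-fill or Egger regression; no odds/risk ratios;
no multi-level or permutation-based meta-regression; clustering offers
no weighted variant, hierarchical method or G-test; digitization does no
OCR or automatic axis detection and has no GUI. The eight quality
checklist items are equally weighted — no validated weighting exists, so
the aggregate score should be read as a count, not a calibrated scale.
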