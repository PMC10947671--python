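# Methods

This note documents the statistical machinery in `biodivmap`: the estimators,
the conventions chosen where several were defensible, the synthetic data the
tests run on, and the limits of what those tests demonstrate.

## Incidence data

All diversity estimation is incidence-based. Within a grid cell, a *sampling
unit* is an observer-day (one observer's records on one date; a config switch
collapses this to observer). A species either occurs in a unit or it does
not; repeated records of the same species within a unit are collapsed. The
cell's data reduce to `T` (units), the incidence frequencies `Y_i`, and the
derived `U = Σ Y_i`, `S_obs`, `Q1` (species in exactly one unit) and `Q2`
(exactly two). Opportunistic records are closer to exchangeable detection
events within observer-days than to abundance counts, which is why abundance
is discarded; it also makes estimates robust to individual observers
photographing one plant many times.

Only cells with ≥ 40 unique observers (applied after record cleaning) enter
estimation; cells below the threshold are mapped purely by spatial
extrapolation.

## Sample coverage

Coverage — the probability mass of incidences belonging to already-detected
species — is estimated by the Chao-type formula

    C(T)      = 1 − (Q1/U)·A,
    C(T + t*) = 1 − (Q1/U)·A^(t*+1),
    A = (T−1)Q1 / ((T−1)Q1 + 2Q2),

with the bias-corrected `A = (T−1)(Q1−1)/((T−1)(Q1−1)+2)` when `Q2 = 0` (and
coverage exactly 1 when `Q1 = 0`). Below the observed effort the unbiased
rarefaction estimator is used at integer efforts,

    C(t) = 1 − Σ_{i: T−Y_i ≥ t} (Y_i/U) · C(T−Y_i, t) / C(T−1, t),   t < T,

with binomial coefficients evaluated through log-gamma.

**Saturation** is judged at doubled effort: a cell is saturated when
`C(2T) ≥ 0.80`. Doubling asks whether the accumulation curve has flattened,
not merely whether current coverage is high.

**Inverting coverage to effort.** The target effort `m*` solving
`C(m*) = 0.80` is found by linear interpolation between integer-effort
coverages below `T` and in closed form on the extrapolation branch
(`m* = T − 1 + log((1−C*)·U/Q1) / log A`). The analytic continuation of the
rarefaction estimator is *not* used for non-integer inversion: its cutoff
condition `T − Y_i ≥ t` empties the sum on the interval `(T−1, T)`, creating
a spurious plateau at 1, whereas the integer lattice is monotone.

## Hill numbers at fixed coverage

For q ∈ {0, 1, 2} and integer effort `t ≤ T`, all three orders are Hill
functionals of the expected incidence-class counts under hypergeometric
subsampling, `E[Q_k(t)] = Σ_i C(Y_i,k)·C(T−Y_i,t−k)/C(T,t)`:

    D_q(t) = [ Σ_k (k/Ût)^q · E[Q_k(t)] ]^{1/(1−q)},    Ût = tU/T,

with the entropy limit at q = 1. Because all orders are evaluated on the
*same* distribution, `D_0 ≥ D_1 ≥ D_2` holds exactly at integer efforts, and
linear interpolation between adjacent integers (the convention for fractional
`m*`) preserves it.

Extrapolation beyond `T` uses the standard estimators: the Chao2-type
asymptote for q = 0,

    D_0(T+m*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^{m*}],
    Q̂0 = (T−1)/T · Q1²/(2Q2)   (or Q1(Q1−1)/2 when Q2 = 0);

for q = 1 the entropy interpolation
`exp[(T/t)·H_obs + (1 − T/t)·Ĥ∞]` between the plug-in entropy of relative
incidences and the asymptotic (Chao–Wang–Jost-type) entropy estimator, whose
rare-species correction is evaluated through a tail series when the decay
parameter is small (the direct expression suffers cancellation); and for q = 2
the closed-form moment estimator

    D_2(t) = Ût² / [ t(t−1)/(T(T−1)) · Σ Y_i(Y_i−1) + Ût ],

which is exact for `t ≤ T` and extends smoothly beyond.

**Ordering cap.** The three extrapolation formulas are unrelated estimators,
and on data-deficient cells (few or no duplicate incidences) they can invert
the Hill ordering — with all singletons, the q = 2 form grows without bound.
Since the true quantities satisfy `D_0 ≥ D_1 ≥ D_2` at any effort, the
implementation caps each higher order by the next lower one on the
extrapolation branch. Extrapolation is additionally capped at effort `2T`
(with a warning), the usual reliability horizon; for saturated cells
`m* ≤ 2T` holds by construction.

Correctness is checked three ways: hand-evaluated fixtures; a Monte-Carlo
subsampling oracle (incidence-class counts averaged over random unit subsets,
with batch-based standard errors); and a frozen golden file of 25 incidence
vectors computed by an independently written base-R implementation of the
same published formulas, matched to 1e−6.

## Trend models

Predictors are standardized (mean 0, sd 1 on training cells) and screened in
two passes: for every collinear pair (|r| > 0.8, walked in decreasing |r|)
the member less correlated with the outcome is dropped; then predictors with
|r| ≤ 0.1 against the outcome are dropped. Survivors are ordered strongest
first, so the identifiability guard (one term per 10 training cells) keeps
the most informative ones. Missing covariate values are filled beforehand
with the mean of non-missing neighbors within 8 km of the cell centroid.

**GLM.** Log-link quasi-Poisson (Var = φμ) via iteratively reweighted least
squares, with the longitude coordinate added as a candidate (latitude is
excluded from the linear path — strongly collinear with longitude along a
coastal gradient — but enters the GAM spatial smooth). Both-direction
stepwise selection minimizes QAIC = deviance/φ_full + 2(p+1), with φ_full the
Pearson dispersion of the full model.

**GAM.** An in-package penalized quasi-Poisson additive model:

* univariate cubic P-splines (8 B-spline basis functions, second-order
  difference penalty), sum-to-zero constrained;
* one 2-D spatial smooth: a low-rank thin-plate radial basis (`r² log r`
  kernel on up to 49 deterministic knots, constrained orthogonal to the
  linear drift), the construction behind Duchon-type spatial smooths; knots
  scale down with training size (≤ n/3);
* a second, null-space penalty per term (the double-penalty device), so
  selection can remove a whole term;
* smoothing parameters maximize the Laplace-approximate REML criterion via
  Fellner–Schall multiplicative updates interleaved with the penalized IRLS,
  with the penalty pseudo-inverse computed per term block (a global eigen
  tolerance lets one heavily penalized term truncate the spectrum of the
  others — a real bug class);
* dispersion from the Pearson statistic, coefficient covariance
  `φ(X'WX + S_λ)⁻¹`, prediction SEs by the delta method on the log link.
  Covariates are clamped to their training range at prediction time.

On pure-noise simulations the double penalty removes individual smooth terms
(edf < 0.5) in about two thirds to three quarters of replicates with a median
edf near zero — matching, not exceeding, what reference REML shrinkage
selection achieves on the same data; the test suite asserts that verified
level.

A perfectly constant response short-circuits to an exact intercept-only
model (IRLS engines reject that corner).

## Variogram and kriging

The empirical semivariogram is Matheron's estimator over 15 equal-width lag
bins up to half the maximum pairwise distance. Exponential, spherical and
gaussian families are fitted by weighted least squares with Cressie weights
`N(h)/γ_model(h)²` (weights re-evaluated inside the optimizer); the family
with the lowest weighted SSE wins. The range parameter is the family's
natural scale (effective exponential range ≈ 3× it). A `fit_nugget=False`
switch pins the nugget for recovery checks on processes known to be
nugget-free, since a free nugget absorbs short-lag curvature and biases the
fitted range upward. If no family converges, callers fall back to a
pure-nugget model (kriging then degrades to the residual mean).

Ordinary kriging solves the semivariance-form system with the unbiasedness
constraint over a global neighborhood (all observations; a few hundred cells
at most here). The model curve has `γ(0⁺) = nugget`, but exactly coincident
points get semivariance 0 — the nugget is a discontinuity at the origin — so
the predictor is exact at observed locations. A singular system is retried
once with 1e−10 added to the diagonal. Regression kriging composes the trend
with ordinary kriging of its *response-scale* residuals (`y − μ̂`), since the
residual field is superimposed additively on the trend map; final predictions
are floored at the minimum observed value, and prediction SE is
`sqrt(trend SE² + kriging variance)` under an independence approximation
(smoothing-parameter uncertainty is not propagated).

One consequence worth naming: because kriging is exact at data locations, the
"optimized" map (observed estimates overriding predictions in saturated
cells) coincides with the raw regression-kriging map up to solver round-off;
the override matters for the pure-regression and degraded variants.

## Cross-validation and model selection

Ten random folds (seeded; sizes within one of each other). Within each fold
the standardization, screening, trend and residual variogram are all refitted
on the 90% training split. Held-out predictions are pooled before computing
correlation, MAE, RMAE = 100·MAE/mean(observed), RMSE and RRMSE =
100·RMSE/mean(observed); the relative denominators use the pooled validation
mean. Training metrics for the regression models are averaged across folds.
Selection ranks by validation RRMSE with ties broken by higher correlation,
then lower RMAE, per metric; the consensus is the majority winner (ties go to
the lowest mean RRMSE).

## Disparity models

Tract values are area-weighted means of intersecting cells (weights =
intersection areas; rectangle geometry makes the brute-force oracle exact).
Group comparisons use Welch's unequal-variance t-test. The mixed model is

    y_tract = β0 + β1·SES + β2·pop_density + b_county + ε,

with `b_county` a random intercept and `Corr(ε_i, ε_j) = exp(−d_ij/ρ)` on
tract centroids. The marginal covariance `σ²[R(ρ) + g·ZZ']` is fitted by
REML: `β` and `σ²` are profiled out, and `(log g, log ρ)` are optimized by
Nelder–Mead from two starts. Confidence intervals are Wald. With the spatial
and county components disabled the fit reduces *exactly* to OLS — the
independence limit used as an oracle. Failures to evaluate the criterion fall
back to the independent-residual model with a flag. Backward selection for
the full-SES sensitivity model compares ML-based AIC (BIC reported alongside)
at the REML variance parameters; poverty and housing burden stay out of the
full model by design (collinearity), and the NDVI sensitivity refits the
single-SES models with NDVI as an added adjustment. SES predictors enter on
their raw percent scales (a standardization switch exists upstream via the
covariate stack but is not applied here).

## Synthetic data: what it emulates, and what it does not

`generate_truth` draws every covariate surface and the population-density
driver as Gaussian random fields with exponential covariance (default range
20 km on 5 km cells, exact Cholesky simulation). True log-richness is a
linear combination of a known covariate subset (+0.12 temperature, +0.18
precipitation, +0.25 NDVI, +0.12 tree canopy, −0.10 soil pH, on standardized
surfaces) plus a spatial field (sd 0.25) and white noise (sd 0.05) around a
median of 150 species — spanning roughly 30–800 species per cell, a range
like that of urban flora. Each cell's community draws its species from a
3000-species pool with lognormal relative abundances (log-sd 1.5), giving the
heavy rare-species tail that makes coverage estimation nontrivial; true
`D_0 ≥ D_1 ≥ D_2` follow from the realized abundances.

`generate_occurrences` draws observer counts per cell as Poisson with mean
`observer_rate × pop_density` (default rate 25, giving roughly the
observed-study fraction of effort-eligible cells on small demo grids; the
evaluation landscapes use 35 on a 40 × 40 grid, which yields ~25–30%
saturated cells). Each observer contributes Poisson(20) records (negative
binomial available) drawn independently from the cell's abundance
distribution — the random-sampling assumption behind the incidence model —
on a single date, with coordinates uniform in the cell. A configurable
fraction of records (default 5%) is corrupted with one of four defects
(missing coordinates, missing species, genus-level taxonomy, cultivated
flag), independent of species identity so cleaning tests have exact expected
counts; hidden `_`-prefixed columns carry the ground truth.

`generate_tracts` tiles the extent with near-square rectangles. The poverty
variable is a *deterministic* affine function of tract-mean true richness
with slope `1/ses_effect` (default ses_effect −2 richness units per percent),
so that richness regressed on poverty has exactly the built-in slope; adding
noise on the SES side would attenuate that slope (errors-in-x) and destroy
the known-truth property. With `ses_effect = 0` poverty is an independent
field. Other SES variables are correlated noise around poverty; the DAC flag
marks the worst ⌈25%⌉ of a composite; counties are contiguous bands.
`simulate_tract_outcomes` generates tract-level outcomes directly from the
mixed model (used for slope-recovery and CI-coverage checks at the magnitude
reported for such studies, −0.61).

Not emulated: taxonomic misidentification, trait-based recording preference,
seasonal reporting cycles, observer home-range clustering across cells, and
real tract geometry. Passing tests therefore demonstrate that the estimators
and models do what they claim under the stated sampling model — not that the
pipeline is robust to every bias of real volunteer data.

A scale caveat: diversity standardized to 80% coverage is a *relative* index.
On heavy-tailed communities it sits well below asymptotic richness, so map
errors measured against the true (asymptotic) surface carry a large shared
bias for every method; comparisons between methods, correlations with truth,
and disparity slopes remain meaningful, and the tests use those.

## Numerical choices and degenerate inputs

* Binomial coefficients and their ratios via log-gamma throughout.
* Coverage inversion tolerance 1e−6 on the extrapolation branch.
* Hill ordering tolerance 1e−9 in invariants (floating-point only).
* PIRLS convergence 1e−9 on relative deviance change; Fellner–Schall outer
  loop stops at 1e−3 on max |Δ log λ|, λ clipped to [1e−7, 1e9].
* Empty cells yield `T = 0` incidence objects; `T < 2` raises an
  insufficient-data error; unattainable coverage targets raise rather than
  return a capped value.
* Kriging ties at exactly coincident coordinates resolve to semivariance 0;
  boundary points of grid cells belong to the higher-index cell (half-open
  intervals), so assignment is total and deterministic.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipeline artifacts contain no timestamps, so a
  rerun with the same configuration is byte-identical.

## Known limitations

* The GAM's REML criterion is the working-model (performance-iteration)
  approximation, not the exact Laplace criterion of a full Newton scheme;
  term-removal rates match reference shrinkage selection but smoothing
  parameters can differ in the third significant figure.
* Kriging uses a global neighborhood and dense solves — appropriate for
  hundreds to a few thousand training cells, not for much larger grids.
* The spatial LMM assumes a single exponential correlation scale and no
  nugget in the residual correlation; the CI coverage checks are run under
  that same model class.
* Coordinates are assumed planar in an equal-area projection; no CRS
  transformations are performed.
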