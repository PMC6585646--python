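# Methods

## The structural system and its assumptions

The package treats log public pharmaceutical expenditure per capita `y` and
log GDP per capita `x` as jointly determined in an annual country panel:

```
y_it = β x_it + μ_y' w_it + α_i + γ_t + ε_it
x_it = δ y_it + μ_x' w_it + π z_it + a_i + g_t + u_it
```

Country effects absorb time-invariant heterogeneity (geography, institutions,
health-system design); year effects absorb common shocks.  Identification of
β rests on an exclusion restriction: the instrument `z` (log tourist
receipts) shifts income but enters the expenditure equation only through
income.  Identification of δ in step 2 additionally assumes the two
structural errors are uncorrelated conditional on controls and effects; if
they are correlated the procedure still removes the reverse-causality bias
but not shared time-varying omitted variables.  The system is solvable iff
|δβ| < 1, which the simulator enforces before drawing.

## Estimators

Two-way effects are absorbed by iterated alternate entity/period demeaning
(tolerance 1e-10 relative to column scale, max 10,000 sweeps — exact in one
sweep on balanced panels), rather than by materializing dummy matrices; the
dummy-matrix regression is retained as a test oracle and the two agree to
1e-8 on random unbalanced panels.  Degrees of freedom subtract
(N−1)+(T−1)+1 for two-way absorption.  Missing data are handled by listwise
deletion per fitted specification.

2SLS uses the generic projection form `b = (R'PzR)^{-1} R'Pz y` with
residuals computed from actual (not fitted) endogenous values.  Variance
flavors: classical, HC1, and entity-clustered with the G/(G−1) correction;
the default is `cluster_entity`, since country-level serial correlation is
the norm in annual panels.  The reported R² is the within-R² and is not
clipped below zero (IV residuals can exceed the within variation).

Diagnostics follow the standard quartet.  The rank-LM underidentification
test is the score form `n·ḡ'S⁻¹ḡ` on the moments g = z⊥·x⊥ with S matched
to the variance flavor; under the classical flavor it reduces to the
Anderson canonical-correlation LM (n·r²).  The Hausman test contrasts FE
with Swamy–Arora feasible-GLS RE (entity variance component truncated at
zero, classical variances, pseudo-inverse fallback flagged).  The
endogeneity test is the Durbin–Wu–Hausman control-function form (first-stage
residual added to the structural equation, flavor-matched Wald), chosen over
the contrast form for numerical stability.  Scope is one endogenous
regressor with k ≥ 1 instruments; every specification the pipeline produces
is exactly identified, so no overidentification test exists.

## The two-step procedure

β̂ used in `y* = y − β̂x` is always estimated on the same listwise-complete
sample as the step-2 fit, so the adjusted series and the income-equation
sample coincide by construction; when a lag or control changes the sample,
step 1 is re-run under the matching specification first.  The defining
algebraic property — IV of y* on x (instrument z) has coefficient exactly
zero when β̂ comes from the same sample — is asserted to 1e-10 in the tests.

The bootstrap resamples entities (pairs-cluster) with replacement, reruns
step 1 → adjustment → step 2 end-to-end per replicate, and reports
across-replicate SDs; replicates failing through rank deficiency are dropped
and counted, with >20% failures an error.  Default 999 replicates.

**Known limitation.** When the step-1 instrument is marginal (first-stage F
near 10–20), the step-2 estimator is a ratio whose denominator
`cov(ỹ, ỹ*) ≈ Var(ε) + β·Var(x̃)·(β − β̂)` can approach zero for large
β̂ excursions: its sampling distribution is then heavy-tailed and SD-based
summaries (bootstrap or Monte-Carlo) are unstable even though the estimator
is median-consistent.  Under strong identification the bootstrap SE matches
the Monte-Carlo SD within ~10%.  Analytic step-2 SEs ignore the
generated-instrument noise entirely and can be close to an order of
magnitude too small; they are emitted for comparability, but the bootstrap
SEs are the ones to report.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study conditions of the motivating application: an
unbalanced panel of 136 countries x 12 years (1995–2006 labels, 15% of cells
missing at random with ≥2 observed years per country), β = 1.4, δ = −0.09,
an AR(1) instrument (ρ_z = 0.7, innovation SD 0.4) around country means
(SD 1.0), country effects drawn with correlation 0.4 to the country-mean
instrument level (so random effects are inconsistent and the Hausman test
has power), year-effect SD 0.1, and structural shock SDs σ_ε = 0.25,
σ_u = 0.10.  The shock scales were calibrated once so that (i) the
full-panel first-stage F lands in the 10–30 range of a credible but not
overwhelming instrument, and (ii) the constructed step-2 instrument is very
strong (its own first-stage F in the hundreds-to-thousands), the regime the
application reports; the asymmetry σ_u < σ_ε also reflects that national
income series are far smoother than public expenditure series.  π defaults
to 0.026 under that calibration.  All randomness flows from one seed through
SeedSequence spawning with a fixed stream order (one child stream per draw
site), so panels are bit-reproducible.

Closed-form within-moments of the solved system (including the exact
demeaned-AR(1) instrument variance and autocovariances) are exposed on
`SimulationTruth` and serve as oracles: the naive-OLS probability limits in
both equations, the positive sign of the reverse-equation OLS bias when
β > 0, and the attenuation of lag-k IV estimates by the instrument's within
autocorrelation ratio.

What the generator does **not** emulate: non-normal or heteroskedastic
shocks, serially correlated structural errors, growth trends, country-size
weighting, or any attempt to reproduce the motivating study's printed
coefficients (impossible without its undeposited data).  Passing recovery
tests therefore demonstrate correctness of the procedure under the assumed
system, not robustness to real-data pathologies.

## Outlier screen

The Hadi forward search starts from the coordinatewise median and a scatter
built from the ⌈(n+p+1)/2⌉ least-outlying points, grows the clean subset one
point at a time by ascending robust Mahalanobis distance (re-estimating
mean/covariance each step, with the small-sample correction factor
1 + (p+1)/(m−p) + 2/(m−1−3p) on the scatter), and stops when the nearest
excluded point exceeds the χ²_p quantile at 1 − α/n.  α defaults to 0.05;
the variables screened default to the (log expenditure, log income) pair on
the balanced panel.  Ties break by original row order; a singular scatter is
ridge-perturbed by 1e-10·trace/p and flagged.  The procedure is
deterministic and affine-equivariant.

## IV quantile regression

Inverse-quantile grid search: for each candidate elasticity b, a check-loss
quantile regression (statsmodels QuantReg) of y − b·x on the instrument,
controls, and entity/year indicator regressors is fitted at τ; the chosen b
minimizes the squared instrument t-ratio, and its SE comes from the delta
method, se(γ̂)/|dγ/db|, with the derivative taken numerically at the
solution.  The default grid is the 2SLS point estimate ± 3 SEs in 121
points; a boundary minimum raises an error instructing a wider grid.  Fixed
effects enter as indicators because within-demeaning is invalid for
quantiles; with T < 15 this carries incidental-parameter bias, and the fit
warns accordingly.

## Problem sizes in the test-suite and acceptance script

Monte-Carlo checks run at the default 136x12 scale with 150–500 replicates
(recovery, diagnostic calibration), 500 replicates at n = 200–500 for the
outlier screen, and compact 24x10 panels with a strong instrument (π = 0.3)
for quantile-IV recovery, where each of the five quantiles requires a full
grid of quantile fits per replicate.  Bootstrap determinism is exercised at
999 replicates on a 60-country panel.  These sizes give Monte-Carlo standard
errors a few times smaller than the effects being verified while keeping the
whole suite quick on a single core.
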