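# Methods

## Scope and data model

The package analyses balanced country-by-year panels: every country
observed in every year of one contiguous run, no missing cells.  The
only external format is a wide CSV (`country,year,<var>,...`); rows are
canonicalised to (country, year) order on load so that every downstream
computation is reproducible byte for byte.  Unbalanced or gappy panels
are rejected rather than repaired — the spline fit, the pooled Granger
regression and the descriptive summaries all assume a rectangular
sample, and silent imputation would change each of them differently.

Variables are log-transformed (natural logarithm) before the screens and
the spline fit by default, which stabilises variance for the strongly
trending macro series; non-positive values are a hard error, with no
offset, because every variable in the emulated panel is strictly
positive.  A levels switch is exposed for sensitivity analysis.

## The spline engine

**Model family.**  f(X) = β₀ + Σ βₘ λₘ(X), with each λₘ a product of up
to `max_degree` one-sided linear splines max(0, x−t) / max(0, t−x),
knots drawn from the observed values of the predictor (no minimum-span
thinning).  A variable may not appear twice within one product term.
`max_degree` defaults to 3: the published model this package emulates
contains three-factor products, even though its surrounding description
speaks of pairwise interaction, so both are reachable (set 2 to force
pairwise).

**Forward pass.**  Greedy growth from the intercept: at each step the
(parent term, new predictor, knot) triple whose reflected hinge pair
most reduces the RSS is added, coefficients refitted by OLS.  Candidate
scoring projects the pair onto the orthogonal complement of the current
basis (one QR factorisation per step, all knots of one parent×predictor
combination evaluated in a single batch); the accepted pair is then
refitted exactly by least squares, so the reported RSS trace is the
plain OLS value.  Near-collinear pairs fall back to the best rank-one
reduction.  A knot at the observed minimum of a predictor has an
identically-zero mirror branch; its surviving branch spans, together
with the parent term, the same space as the bare variable, so it is
represented and reported as a *linear* factor (the published model
contains such a bare-variable factor).  Ties are broken
deterministically: lower created-term degree, earlier predictor order,
smaller knot; candidates within 1e-12 of the incumbent's reduction do
not replace it.  Growth stops at `max_terms` (intercept included,
default 21) or when the relative RSS improvement falls below 1e-10.
Constant predictors and constant responses yield the intercept-only
model, not an error.

**Backward pass.**  From the full forward model, the single term whose
deletion gives the lowest GCV is removed, repeatedly, down to the
intercept; every visited subset is recorded with its refitted RSS and
GCV, and the global GCV minimiser of the trace is returned, refitted by
OLS.  Subsets whose effective parameter count reaches the sample size
(possible at very small n) are traced with GCV = ∞ and can never be
selected.  GCV differences below 1e-10 of the intercept-only GCV are
treated as numerical noise and resolved toward the smaller subset; this
matters only for exact-interpolation fits, where every superset of the
true terms has RSS ≈ 0 and the tie-break removes zero-coefficient
leftovers.

**Effective parameters.**  Two conventions are implemented.  The default
`knot_penalty` sets C = M + d·(M−1)/2 with d = 3: M coefficients plus a
penalty d per reflected hinge pair.  This convention reproduces the
published model's printed GCV (0.03863691) exactly from its printed RSS,
N and term count, which the text's own formula ((λ+1)+dλ with d = 2,
available as `eq4`) does not (it gives ≈ 0.0401); both are kept because
the discrepancy is in the source, not in this implementation.

**Fit measures.**  RSq = 1 − RSS/TSS; GRSq = 1 − GCV/GCV_null with the
intercept-only model (one effective parameter) as reference.  For a
constant response (TSS = 0) the fit functions raise, and the top-level
`fit` reports 0 for both measures.

**Variable importance.**  For each predictor: the number of pruning
subsets containing at least one term using it, and the GCV (RSS)
increase accumulated whenever a term using it is deleted along the
trace, clipped below at zero (a variable whose deletions never cost
anything scores 0, not negative) and rescaled so the top used variable
scores 100.  Predictors absent from the final model are reported as
unused with no scores, mirroring the "–" convention of the source
study's importance table.

## Econometric screens

**2SLS / Hausman.**  Two-stage least squares is computed directly: the
endogenous columns are projected on [exogenous, instruments], the second
stage is OLS on [exogenous, fitted endogenous], and residuals (hence the
classical covariance s²(Ŵ′Ŵ)⁻¹) are taken against the original
regressors.  The Hausman statistic uses the matrix-difference form with
a symmetrised covariance difference, negative eigenvalues clipped at
zero, and a pseudo-inverse, so H ≥ 0 always; df equals the number of
instrumented coefficients compared.  The OLS legs go through
statsmodels; 2SLS is implemented here because the installed statsmodels
exposes no instrumental-variable estimator.

**Stacked Granger causality.**  Lags are built within each country (no
cross-border lags); all countries are pooled into one
common-coefficient regression with a single constant (no country
intercepts — the "common coefficients" reading), and the joint nullity
of the cause lags is F-tested with df (L, n_obs − 2L − 1).  By default
the series are first-differenced within each country before lag
construction: this is the standard stationarity treatment for trending
macro panels, and it is the convention under which a 14-country ×
23-year panel with two lags yields the 280 pooled observations (and
denominator df 275) reported in the source study — without
differencing the same panel keeps 294.  `difference=False` runs the
test on the series as given; the Monte-Carlo calibration tests use it
because their generated series are already stationary, so no
differencing step is warranted there.

**Distribution tails.**  Chi-square and F upper tails are thin validated
wrappers over scipy.stats; the test suite checks them against the
closed forms e^{−x/2} (chi-square, df 2), 2(1−Φ(√x)) + √(2x/π)e^{−x/2}
(df 3) and (1+2x/df₂)^{−df₂/2} (F, df₁ = 2) to 12 decimals.

## Synthetic generators

`gen_panel` draws, per country and variable, a stationary Gaussian AR(1)
series z_t = ρ z_{t−1} + √(1−ρ²) ε_t, scales it to the target mean and
standard deviation and clips to [min, max].  The shipped moment file
mirrors the study's descriptive-statistics table for all seven
variables; its HEALTH row is corrected (mean 6.4149, sd 1.0745) because
the printed mean 64.149, sd 10.745 and variance 11.546 are mutually
inconsistent with the printed coefficient of variation (16.75) and
range (5.2).  Persistence ρ = 0.8 was fixed once as representative of
highly persistent macro panels; neither the study nor its summary
tables state a serial-correlation level.  Clipping is applied after
moment matching (range fidelity prioritised; the induced sd shrinkage
is within the tolerance of the moment-recovery tests, which use
autocorrelation-adjusted standard errors with effective sample size
n(1−ρ)/(1+ρ)).

What the generator does *not* emulate: cross-country correlation,
deterministic trends, measurement revisions, or any structural link
between life expectancy and the expenditure variables — its default
response is independent of the predictors.  Passing tests on synthetic
panels therefore demonstrate correctness of the algorithms and
calibration of the tests, not the substantive findings on the real
Eurostat/KOF data.

`gen_piecewise_response` evaluates a known hinge-product signal (knots
must be observed values, so they are recoverable exactly) plus optional
Gaussian noise; `gen_figure1_grid` returns the exact surface
sin(1.5πx₁)cos(0.5πx₂) on a uniform grid; `gen_endogenous_system` and
`gen_granger_pair` are the calibration beds for the two screens, with
known endogeneity correlation and known lag-1 causal coefficient
respectively.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: spline fits
on 41–441 observations, forward-search oracles at n ≤ 20 (exhaustive
enumeration over all knots), screen calibrations at 1000 Monte-Carlo
replicates of the study-shaped 14×23 panel (type-I error within three
binomial standard errors of the nominal 0.05, Kolmogorov–Smirnov
uniformity of null p-values), and power checks at the study's own
sample sizes.  All randomness flows through numpy `default_rng` seeds;
identical seeds give bitwise-identical models, reports and result
files.  Least squares uses `numpy.linalg.lstsq` (minimum-norm on rank
deficiency) throughout, so duplicated or collinear basis columns are
harmless.

## Known limitations

* Smoothed (cubic) spline variants, categorical predictors and fast
  update formulas for the forward pass are out of scope; the naive
  refit is transparent and is itself the oracle for the batched search.
* The residual-diagnostic route of the source study (its three named
  outlier points) has no stated detection rule; ranked absolute
  residuals are available from `predict`, but no automatic exclusion is
  performed.
* Heteroskedasticity-robust covariances, unit-root pre-tests and the
  per-country-coefficient (Dumitrescu–Hurlin) causality variant are not
  implemented; the source study itself deemed the latter infeasible at
  this sample size.
* The published model's coefficients, knots and importance scores are
  functions of the undeposited source panel and cannot be reproduced;
  the package reproduces every printed quantity that is a closed
  function of printed inputs, and validates the algorithms by synthetic
  recovery instead.
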