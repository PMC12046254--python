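# Methods note

This note states precisely what `trendmed` computes, in the package's own
notation. Y is monthly mean excess search volume, X is the monthly mean
daily COVID-19 death count, M is the monthly mean residential-mobility
change (the stay-at-home measure). Panels are country × calendar-month
within an income-group × pandemic-year stratum.

## 1. Counterfactual baseline and excess search volume

For each country-term weekly series on the 0–100 relative scale, a
seasonal ARIMA model (p,d,q)(P,D,Q)_m with m = 52 weeks is fitted to the
baseline window (default March 1, 2015 – February 29, 2020; the window
must end exactly one day before the pandemic window starts, and 2020 is a
leap year). The fitted model is extrapolated over the pandemic window
(default March 1, 2020 – February 28, 2022) as the expected "no outbreak"
volume with normal-theory 95% prediction intervals. Weekly excess is
observed minus expected, unclipped (it may be negative, and may exceed the
0–100 scale's range).

Order selection is the stepwise Hyndman–Khandakar scheme, implemented
directly on `statsmodels` SARIMAX:

- D ∈ {0, 1} from STL seasonal strength, one seasonal difference when
  `1 − var(remainder)/var(seasonal + remainder)` exceeds 0.64;
- d ∈ {0, 1, 2} by successive KPSS level-stationarity tests on the
  seasonally differenced series (difference while the test rejects at 5%);
- (p, q, P, Q) by an AICc-guided neighborhood search from four standard
  starting models — (2,d,2)(1,D,1), (0,d,0)(0,D,0), (1,d,0)(1,D,0),
  (0,d,1)(0,D,1) — moving one step in p, q, P, Q or toggling the constant
  (allowed when d + D ≤ 1) while AICc improves, with bounds p,q ≤ 5,
  P,Q ≤ 2 and at most 60 fitted candidates. All AICc comparisons happen at
  a fixed (d, D), the condition for comparable likelihoods.

## 2. Panel construction

Daily exposure and mediator series are averaged over calendar months
(partial months use the available days). Each excess week belongs to the
month containing its *start* date — a week starting February 27 counts
toward February even though most of it falls in March. The three monthly
streams are inner-joined per country; countries contributing fewer than
two months are dropped with a warning. Pandemic years follow the study
calendar: year 1 = March 2020 – February 2021, year 2 = March 2021 –
February 2022, year 3 = March – October 2022 (an 8-month stratum).

## 3. Mediation decomposition

Within each stratum, three least-squares regressions absorb country and
calendar-month fixed effects by iterated demeaning (alternating
projections; the coefficient estimates equal explicit dummy-variable OLS
to machine precision, which the test suite asserts at 1e-8):

- model 1: Y ~ X, coefficient θ_T (total effect);
- model 2: Y ~ X + M, coefficients θ_A (alternative/direct effect) and β;
- model 3: M ~ X, coefficient α.

The mediation effect is the product of coefficients θ_M = α̂·β̂ with the
Sobel delta-method variance var(θ_M) = β̂²·var(α̂) + α̂²·var(β̂). Because all
three regressions use the same within-transformed data, the product
estimator coincides with the difference estimator θ_T − θ_A exactly, so
θ_T = θ_M + θ_A holds to numerical precision on every output (asserted at
1e-10).

The default coefficient covariance is classical OLS,
σ̂²(X'X)⁻¹ on the demeaned data with residual degrees of freedom
n − k − (C−1) − (T−1) − 1 for C countries and T months. A CR1
cluster-robust (by country) covariance is available via
`cluster_by_country=True`, and `bootstrap_se` provides a country-level
nonparametric bootstrap (resampled countries are relabeled so duplicates
act as separate fixed-effect units). On default synthetic scenarios the
delta-method SE of θ_M agrees with the 500-resample bootstrap within a few
percent on average (mean ratio ≈ 1.03 with ~11% spread across replicate
strata).

## 4. Proportion mediated

PM = 100·θ_M/θ_T, in percent. Its delta-method variance uses the ratio
formula

    var(PM)/PM² = var(θ_M)/θ_M² + var(θ_T)/θ_T² − 2·cov(θ_M, θ_T)/(θ_M·θ_T)

with cov(θ_M, θ_T) approximated by var(θ_M): from θ_T = θ_M + θ_A,
cov(θ_M, θ_T) = var(θ_M) + cov(θ_M, θ_A), and the cross term is taken as
zero. Two documented edge behaviors:

- when the approximation drives the variance below zero, it is floored at
  zero with a warning; the resulting Effect has a degenerate (point) CI
  and an undefined p-value, rendered as "NA" in tables;
- θ_M = 0 degenerates the ratio formula, and the variance falls back to
  (100/θ_T)²·var(θ_M);
- |θ_T| < 1e-12 raises an error — PM is undefined.

CIs are estimate ± 1.96·SE throughout, unconstrained: PM intervals far
outside [0, 100]% are expected for noisy ratios. No multiple-testing
correction is applied.

PM is a ratio of two noisy estimates and is therefore itself very noisy
whenever θ_T is small or the outcome is measured with error. In
particular, estimates computed from forecast-estimated excess (the full
pipeline) carry the counterfactual forecast error as outcome noise and
show much wider PM spreads than estimates on exactly measured excess.

## 5. Synthetic ground truth and verification

The scenario generator produces, per country: Gaussian-wave daily death
curves; monthly mobility M = α·E + intercept + noise (E the monthly mean
death count); weekly baseline search volume = level + 52-week sinusoid +
AR(1) noise, clipped to [0, 100] (scenarios clipping more than 1% of
baseline weeks are rejected); and injected pandemic excess
γ·E + β·M + month effect + noise. The implied truths are
θ_T = γ + α·β and PM = 100·α·β/(γ + α·β); the defaults give θ_T = 10⁻³
and PM = 30%. All randomness derives from a single seed through named
substreams, so adding countries or terms never perturbs existing draws.

One construction detail: with *every* noise source at zero the mediator is
exactly α·E + intercept and model 2 is exactly collinear (β and γ cannot
be separated; the engine raises a clear error). Exact-recovery checks
therefore use `noise_free_panel`, which injects exogenous mediator
variation constructed orthogonal to the within-transformed exposure —
identification is then exact and the decomposition is recovered to ~1e-10.

Verified calibration on the default scenario (see `tests/test_acceptance.py`):
mean estimated PM within 5 percentage points of 30% over 200 seeds; 95%
CI for θ_T covers the truth in 90–98% of 500 replicates; under α = 0 the
θ_M test's type-I error at nominal 5% lies in [2%, 9%] over 1000
replicates (the delta-method test is conservative at these sizes); 95%
forecast bands cover 88–99% of future observations on AR(1) replicates.
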