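# trendmed

Excess search-volume estimation and stay-at-home mediation analysis for
country-level infodemiology panels.

## The scientific problem

During the COVID-19 pandemic, population mental-health strain left a trace
in what people searched for online: queries like "insomnia" and "suicide"
moved away from their seasonal baselines. Two candidate mechanisms compete
to explain that movement. The pandemic's direct toll (deaths, fear,
bereavement) could drive it; or the *behavioral response* — staying at
home — could, through isolation, disrupted routines and reduced social
contact. Distinguishing the two matters because only the second is a
policy-modifiable pathway.

`trendmed` implements the full analysis chain for this question:

1. **Excess search volume.** For each country and search term, a seasonal
   ARIMA model is fitted to five years of pre-pandemic weekly relative
   search volume (0–100 scale) and extrapolated over the pandemic horizon
   as the counterfactual "no outbreak" expectation with a 95% band. Weekly
   *excess* is observed minus expected. Orders are selected automatically
   by a stepwise Hyndman–Khandakar scheme (unit-root tests for the
   differencing orders, AICc-guided neighborhood search for the rest).
2. **Panel assembly.** Daily COVID-19 death counts (exposure) and daily
   residential-mobility change (mediator, percentage points relative to a
   Jan–Feb 2020 baseline) are averaged into calendar months and
   inner-joined with monthly mean excess (outcome) into a country × month
   panel, stratified by World Bank income group (31 high-income, 14
   middle-income countries) and pandemic year (year 1 = Mar 2020–Feb 2021,
   year 2 = Mar 2021–Feb 2022, year 3 = Mar–Oct 2022).
3. **Causal mediation analysis.** Three regressions per stratum, each
   absorbing country and calendar-month fixed effects:
   Y ~ X (total effect θ_T), Y ~ X + M (alternative/direct effect θ_A and
   β), M ~ X (α). The mediation effect is the product of coefficients
   θ_M = α·β with a Sobel delta-method variance; the proportion mediated is
   PM = 100·θ_M/θ_T with a delta-method ratio variance. A country-level
   nonparametric bootstrap is available as an independent check on all
   standard errors.

A fully parameterized synthetic scenario generator with known ground truth
(true total effect, true PM) backs the test suite: every statistical claim
the package makes is checked against either an analytic oracle, an
independent implementation, or Monte-Carlo calibration.

## Worked example

Estimate the mediation decomposition on a synthetic 45-country scenario
whose ground truth is PM = 30%:

```python
from trendmed import default_scenario, simulate_panel, mediate_stratum

truth = default_scenario(seed=42)            # 45 countries, 24 months, true PM 30%
panel = simulate_panel(truth, term="insomnia")
print("panel rows:", len(panel), "countries:", panel.data["country"].nunique())

est = mediate_stratum(panel.stratum("high", 1))   # high income, pandemic year 1
print(f"total effect       : {est.total.estimate:.2e}")
print(f"mediation effect   : {est.mediation.estimate:.2e}  (p={est.mediation.p:.3f})")
print(f"proportion mediated: {est.pm.estimate:.1f}%  (scenario truth: {truth.proportion_mediated:.1f}%)")
```

Output:

```
panel rows: 1080 countries: 45
total effect       : 1.06e-03
mediation effect   : 3.83e-04  (p=0.003)
proportion mediated: 36.2%  (scenario truth: 30.0%)
```

The full pipeline (counterfactual forecasting included) runs from a YAML
config through one command:

```yaml
# config.yaml
mode: synthetic
terms: [insomnia]
sarima_order: [0, 0, 0, 0, 1, 0]   # fixed seasonal-walk spec; omit for automatic selection
outdir: out
seed: 7
```

```sh
trendmed all --config config.yaml
```

writes `excess_insomnia.csv`, `panel_insomnia.csv`, `mediation_insomnia.csv`
(+ `.json`), a formatted `table_insomnia.txt` in the published three-block
layout, and a `manifest.json` with the config hash and row counts. Example
table block (synthetic data, seed 7):

```
income_group              effect y1_estimate               y1_ci  y1_p y2_estimate               y2_ci  y2_p
        high               total     7.7e-04  5.2e-04 to 1.0e-03 0.000     9.1e-04  6.2e-04 to 1.2e-03 0.000
        high           mediation    -7.9e-04 -1.9e-03 to 3.6e-04 0.178     1.2e-03  1.3e-04 to 2.3e-03 0.028
        high         alternative     1.6e-03  3.8e-04 to 2.7e-03 0.009    -3.1e-04 -1.4e-03 to 8.1e-04 0.586
        high proportion_mediated      -102.9     -366.8 to 161.1 0.445       134.5      134.5 to 134.5    NA
```

Note the difference between the two examples: `simulate_panel` measures the
injected excess exactly, while the full pipeline *estimates* it by
counterfactual forecasting. The forecast error acts as outcome measurement
noise, so per-stratum mediation estimates and PM (a ratio) are far noisier
in the second case — CIs spilling far outside [0, 100]% are expected
behavior, not a bug. A `y1_ci` collapsing to a point with `p = NA` marks a
stratum where the delta-method PM variance was floored at zero (see
`docs/methods.md`).

Other subcommands: `trendmed simulate` writes a synthetic scenario's input
CSVs in the public-data dialects the readers accept; `trendmed mediate`
re-runs the mediation stage on a previously written panel CSV.

## Reproduction

Run the test suite (about 3 minutes; the acceptance tests in
`tests/test_acceptance.py` cover arithmetic identities, noise-free
recovery, 200-seed parameter recovery, CI coverage and type-I calibration,
oracle equivalences, forecast-band coverage, and the registry partition):

```sh
python -m pytest -q
```

Recompute the package's headline quantities (Monte-Carlo PM recovery,
coverage rates, noise-free decomposition, a full pipeline run) into a JSON
file — deterministic given the seed:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Limitations

- Real Google Trends / mobility / mortality extracts are not bundled; the
  `files` mode reads user-supplied CSVs in the documented dialects, and all
  bundled verification runs on synthetic data with known truth.
- The default coefficient covariance is classical OLS on the
  within-transformed data; cluster-robust (by country) covariance is
  available via a flag but serial correlation within countries is otherwise
  the user's concern. The country bootstrap is the recommended check.
- The PM ratio variance uses a documented approximation for
  cov(θ_M, θ_T); see `docs/methods.md`.
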