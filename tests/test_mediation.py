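"""Fixed-effects mediation: OLS oracle, identities, equivariances."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from trendmed.mediation import (
    Effect,
    bootstrap_se,
    decompose,
    fit_twoway_fe,
    mediate_stratum,
    proportion_mediated,
    run_mediation,
)
from trendmed.synthetic import noise_free_panel, simulate_panel


def _noisy_panel(n_countries=4, n_months=6, seed=0):
    """Small raw panel DataFrame with genuinely noisy columns."""
    rng = np.random.default_rng(seed)
    n = n_countries * n_months
    ci = np.repeat(np.arange(n_countries), n_months)
    ti = np.tile(np.arange(n_months), n_countries)
    exposure = rng.uniform(0, 500, n)
    mediator = 0.01 * exposure + rng.normal(8, 3, n_countries)[ci] + rng.normal(0, 1, n)
    outcome = (
        7e-4 * exposure + 0.03 * mediator
        + rng.normal(0, 1, n_countries)[ci] + rng.normal(0, 0.5, n_months)[ti]
        + rng.normal(0, 0.5, n)
    )
    months = pd.period_range("2020-03", periods=n_months, freq="M")
    return pd.DataFrame(
        {
            "country": np.array([f"C{i}" for i in range(n_countries)])[ci],
            "month": months[ti],
            "exposure": exposure,
            "mediator": mediator,
            "outcome": outcome,
            "income_group": "high",
            "pandemic_year": 1,
        }
    )


class TestTwoWayFE:
    def test_matches_dummy_variable_ols_oracle(self):
        """Absorbed fixed effects must reproduce the explicit-dummy OLS
        coefficients and classical standard errors."""
        df = _noisy_panel()
        fit = fit_twoway_fe(df, "outcome", ["exposure", "mediator"])
        ref = smf.ols(
            "outcome ~ exposure + mediator + C(country) + C(month)",
            df.assign(month=df["month"].astype(str)),
        ).fit()
        for name in ("exposure", "mediator"):
            assert fit.params[name] == pytest.approx(ref.params[name], abs=1e-8)
            assert fit.se(name) == pytest.approx(ref.bse[name], abs=1e-8)
        assert fit.df_resid == int(ref.df_resid)

    def test_outcome_shift_invariance(self):
        df = _noisy_panel(seed=1)
        a = fit_twoway_fe(df, "outcome", ["exposure"])
        b = fit_twoway_fe(df.assign(outcome=df["outcome"] + 1000.0), "outcome", ["exposure"])
        assert a.params["exposure"] == pytest.approx(b.params["exposure"], abs=1e-9)
        assert a.se("exposure") == pytest.approx(b.se("exposure"), abs=1e-9)

    def test_collinear_regressors_rejected(self):
        df = _noisy_panel(seed=2)
        df["mediator"] = 2.0 * df["exposure"]
        with pytest.raises(ValueError, match="singular|no within-variance"):
            fit_twoway_fe(df, "outcome", ["exposure", "mediator"])

    def test_country_constant_regressor_rejected(self):
        df = _noisy_panel(seed=3)
        df["mediator"] = df["country"].map({"C0": 1.0, "C1": 2.0, "C2": 3.0, "C3": 4.0})
        with pytest.raises(ValueError, match="no within-variance"):
            fit_twoway_fe(df, "outcome", ["exposure", "mediator"])

    def test_needs_two_countries(self):
        df = _noisy_panel()
        with pytest.raises(ValueError, match=">= 2 countries"):
            fit_twoway_fe(df[df["country"] == "C0"], "outcome", ["exposure"])


class TestDecomposition:
    def test_exact_recovery_on_noise_free_panel(self):
        est = mediate_stratum(noise_free_panel(alpha=2.0, beta=3.0, gamma=4.0, seed=5))
        assert est.mediation.estimate == pytest.approx(6.0, abs=1e-8)
        assert est.alternative.estimate == pytest.approx(4.0, abs=1e-8)
        assert est.total.estimate == pytest.approx(10.0, abs=1e-8)
        assert est.pm.estimate == pytest.approx(60.0, abs=1e-8)

    def test_product_equals_difference_identity(self):
        est = mediate_stratum(_noisy_panel(n_countries=6, n_months=10, seed=7))
        assert est.total.estimate == pytest.approx(
            est.mediation.estimate + est.alternative.estimate, abs=1e-10
        )

    def test_exposure_rescale_equivariance(self):
        """Measuring the exposure in units 10x smaller (cases vs deaths, say)
        multiplies every effect by 10 and leaves PM unchanged."""
        df = _noisy_panel(n_countries=6, n_months=10, seed=8)
        a = mediate_stratum(df)
        b = mediate_stratum(df.assign(exposure=df["exposure"] / 10.0))
        for name in ("total", "mediation", "alternative"):
            ea, eb = getattr(a, name), getattr(b, name)
            assert eb.estimate == pytest.approx(10 * ea.estimate, rel=1e-9)
            assert eb.se == pytest.approx(10 * ea.se, rel=1e-9)
        assert b.pm.estimate == pytest.approx(a.pm.estimate, rel=1e-9)

    def test_decompose_requires_mediator_in_model2(self):
        df = _noisy_panel(seed=9)
        m1 = fit_twoway_fe(df, "outcome", ["exposure"])
        m3 = fit_twoway_fe(df, "mediator", ["exposure"])
        with pytest.raises(ValueError, match="mediator"):
            decompose(m1, m1, m3)

    def test_run_mediation_unstratified_is_single_estimate(self, tiny_truth):
        panel = simulate_panel(tiny_truth)
        out = run_mediation(panel, stratify=False)
        assert len(out) == 1
        assert out[0].n_countries == 4

    def test_run_mediation_stratified_labels(self, tiny_truth):
        panel = simulate_panel(tiny_truth)
        out = run_mediation(panel)
        labels = {(e.income_group, e.pandemic_year) for e in out}
        assert labels == {("high", 1), ("high", 2), ("middle", 1), ("middle", 2)}
        rows = pd.concat([e.to_rows() for e in out], ignore_index=True)
        assert len(rows) == 4 * len(out)


class TestProportionMediated:
    def test_simple_ratio(self):
        eff = proportion_mediated(3.0, 10.0)
        assert eff.estimate == 30.0 and eff.se == 0.0

    def test_zero_total_effect_undefined(self):
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(1.0, 0.0)

    def test_zero_mediation_gives_zero_pm_with_fallback_se(self):
        eff = proportion_mediated(0.0, 2.0, var_m=4.0)
        assert eff.estimate == 0.0
        assert eff.se == pytest.approx(100.0 / 2.0 * 2.0)  # 100/theta_t * sd_m

    def test_negative_variance_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            eff = proportion_mediated(1.0, 1.5, var_m=1.0, var_t=0.1)
        assert eff.se == 0.0 and np.isnan(eff.p)

    def test_delta_se_formula(self):
        theta_m, theta_t, var_m, var_t = 2.0, 5.0, 0.04, 0.09
        eff = proportion_mediated(theta_m, theta_t, var_m, var_t)
        rel = var_m / theta_m**2 + var_t / theta_t**2 - 2 * var_m / (theta_m * theta_t)
        assert eff.se == pytest.approx(abs(eff.estimate) * np.sqrt(rel), rel=1e-12)


class TestEffect:
    def test_ci_and_p(self):
        eff = Effect(2.0, 1.0)
        assert eff.lower95 == pytest.approx(2.0 - 1.959963984540054, abs=1e-9)
        assert eff.upper95 == pytest.approx(2.0 + 1.959963984540054, abs=1e-9)
        assert eff.p == pytest.approx(0.04550026, abs=1e-6)

    def test_degenerate_se_gives_nan_p(self):
        assert np.isnan(Effect(1.0, 0.0).p)


class TestBootstrap:
    def test_returns_positive_finite_ses(self):
        ses = bootstrap_se(_noisy_panel(n_countries=6, n_months=10, seed=11),
                           n_boot=30, seed=1)
        assert set(ses) == {"total", "mediation", "alternative", "pm"}
        assert all(np.isfinite(v) and v > 0 for v in ses.values())
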