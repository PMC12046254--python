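"""Counterfactual forecasting and excess: oracles and invariances."""

import numpy as np
import pandas as pd
import pytest

from trendmed.excess import (
    ForecastSeries,
    SarimaSpec,
    compute_excess,
    estimate_excess,
    excess_frame,
    forecast_expected,
    seasonal_strength,
    select_order,
)
from trendmed.ingest import WeeklySeries


class TestSarimaSpec:
    def test_negative_order_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SarimaSpec(-1, 0, 0)

    def test_overdifferencing_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            SarimaSpec(0, 3, 0)

    def test_str_is_readable(self):
        assert str(SarimaSpec(1, 0, 2, 0, 1, 1, 52)) == "(1,0,2)(0,1,1)[52]"


class TestForecastSeries:
    def test_band_must_bracket_point_forecast(self, weekly_index):
        idx = weekly_index(4)
        mid = pd.Series([1.0, 2, 3, 4], index=idx)
        with pytest.raises(ValueError, match="bracket"):
            ForecastSeries(expected=mid, lower95=mid + 1, upper95=mid + 2)

    def test_index_mismatch_rejected(self, weekly_index):
        mid = pd.Series([1.0, 2], index=weekly_index(2))
        off = pd.Series([0.0, 1], index=weekly_index(2, start="2016-01-03"))
        with pytest.raises(ValueError, match="indexes differ"):
            ForecastSeries(expected=mid, lower95=off, upper95=mid + 1)


class TestOrderSelection:
    def test_zero_variance_series_rejected(self, weekly_index):
        s = pd.Series(np.full(120, 42.0), index=weekly_index(120))
        with pytest.raises(ValueError, match="zero variance"):
            select_order(s, m=12)

    def test_too_short_for_seasonal_period_rejected(self, weekly_index):
        s = pd.Series(np.arange(30.0), index=weekly_index(30))
        with pytest.raises(ValueError, match=">= 104"):
            select_order(s, m=52)

    def test_pure_sine_gets_one_seasonal_difference(self, weekly_index):
        n, m = 96, 12
        y = 50 + 10 * np.sin(2 * np.pi * np.arange(n) / m)
        assert seasonal_strength(y, m) > 0.9
        spec = select_order(pd.Series(y, index=weekly_index(n)), m=m)
        assert spec.D == 1 and spec.m == m

    def test_white_noise_stays_small(self, weekly_index):
        rng = np.random.default_rng(7)
        y = pd.Series(50 + rng.normal(0, 1, 180), index=weekly_index(180))
        spec = select_order(y, m=12)
        assert spec.d == 0 and spec.D == 0
        assert spec.p + spec.q + spec.P + spec.Q <= 2

    def test_ar1_beats_brute_force_oracle(self, ar1_series):
        """The stepwise pick's AICc sits within 2 units of the exhaustive
        minimum over all non-seasonal (p, q) up to 2 at the same (d, D)."""
        from trendmed.excess import _fit_candidate

        y = ar1_series(phi=0.5, n=260, seed=0)
        spec = select_order(y, m=1)
        assert spec.d == 0  # AR(1) phi=0.5 is comfortably level-stationary
        assert spec.p + spec.q >= 1
        brute = []
        for p in range(3):
            for q in range(3):
                cand = SarimaSpec(p, spec.d, q, m=1, include_constant=spec.include_constant)
                out = _fit_candidate(y.to_numpy(), cand)
                if out is not None:
                    brute.append(out[1])
        assert spec.aicc <= min(brute) + 2.0


class TestForecastAndExcess:
    def test_constant_series_forecast_recovers_level(self, weekly_index):
        rng = np.random.default_rng(0)
        y = pd.Series(60 + rng.normal(0, 1e-4, 120), index=weekly_index(120))
        fc = forecast_expected(y, SarimaSpec(0, 0, 0, include_constant=True), horizon=10)
        assert np.allclose(fc.expected, 60.0, atol=0.01)
        assert len(fc) == 10
        # forecast index continues the weekly grid
        assert fc.week_start_dates[0] - y.index[-1] == pd.Timedelta(days=7)

    def test_pure_sine_extrapolates_exactly(self, weekly_index):
        n, m = 120, 12
        t = np.arange(n + 24)
        y = 50 + 10 * np.sin(2 * np.pi * t / m)
        baseline = pd.Series(y[:n], index=weekly_index(n))
        fc = forecast_expected(baseline, SarimaSpec(0, 0, 0, 0, 1, 0, m), horizon=24)
        assert np.allclose(fc.expected.to_numpy(), y[n:], atol=1e-3)

    def test_excess_is_observed_minus_expected(self, weekly_index):
        idx = weekly_index(5)
        obs = pd.Series([50.0, 52, 54, 53, 51], index=idx)
        fc = ForecastSeries(
            expected=pd.Series(50.0, index=idx),
            lower95=pd.Series(48.0, index=idx),
            upper95=pd.Series(52.0, index=idx),
        )
        exc = compute_excess(obs, fc, country_code="AU", term="insomnia")
        assert np.allclose(exc.values, [0, 2, 4, 3, 1])

    def test_mismatched_dates_name_first_offender(self, weekly_index):
        idx = weekly_index(3)
        fc = ForecastSeries(
            expected=pd.Series(50.0, index=idx),
            lower95=pd.Series(48.0, index=idx),
            upper95=pd.Series(52.0, index=idx),
        )
        obs = pd.Series([1.0, 2, 3], index=weekly_index(3, start="2015-03-08"))
        with pytest.raises(ValueError, match="first mismatch"):
            compute_excess(obs, fc)

    def test_excess_linearity_in_observed(self, weekly_index):
        idx = weekly_index(4)
        fc = ForecastSeries(
            expected=pd.Series([10.0, 11, 12, 13], index=idx),
            lower95=pd.Series(5.0, index=idx),
            upper95=pd.Series(20.0, index=idx),
        )
        obs = pd.Series([12.0, 14, 13, 15], index=idx)
        base = compute_excess(obs, fc).values
        shifted = compute_excess(obs + 5.0, fc).values
        assert np.allclose(shifted - base, 5.0)

    def test_estimate_excess_end_to_end_on_noisefree_seasonal(self, quiet_truth):
        from trendmed.synthetic import generate_baseline_search, structural_excess

        series = generate_baseline_search(quiet_truth, "AU", "insomnia")
        exc = estimate_excess(
            series,
            baseline_end="2020-02-29",
            pandemic_start="2020-03-01",
            pandemic_end="2022-02-28",
            spec=SarimaSpec(0, 0, 0, 0, 1, 0, 52),
        )
        injected = structural_excess(quiet_truth, "AU", "insomnia")
        # the 52-week sine repeats exactly, so the seasonal-walk forecast is
        # the exact counterfactual and estimated excess equals injected excess
        assert np.allclose(exc.values.to_numpy(), injected.to_numpy(), atol=1e-6)


class TestExcessFrame:
    def test_tidy_schema(self, weekly_index):
        idx = weekly_index(3)
        fc = ForecastSeries(
            expected=pd.Series(50.0, index=idx),
            lower95=pd.Series(48.0, index=idx),
            upper95=pd.Series(52.0, index=idx),
        )
        obs = WeeklySeries("IT", "suicide", pd.Series([55.0, 54, 53], index=idx))
        df = excess_frame(compute_excess(obs, fc))
        assert list(df.columns) == [
            "country", "term", "week_start", "excess",
            "observed", "expected", "lower95", "upper95",
        ]
        assert (df["country"] == "IT").all() and len(df) == 3
        assert np.allclose(df["excess"], df["observed"] - df["expected"])
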