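"""Counterfactual expected search volume and weekly excess.

A seasonal ARIMA model is fitted to the pre-pandemic search-volume window
(five years, March 2015 - February 2020 in the study configuration) and
extrapolated over the pandemic horizon as the counterfactual "no outbreak"
expectation with normal-theory 95% intervals.  Weekly excess is observed
minus expected, unclipped.

Order selection follows the Hyndman-Khandakar stepwise scheme: the seasonal
differencing order D comes from a seasonal-strength threshold, the
differencing order d from successive KPSS tests on the seasonally
differenced series, and (p, q, P, Q) from an AICc-guided neighborhood search
started at four standard models.  All candidate AICc values are compared
within a fixed (d, D), which the search never varies -- the requirement for
valid likelihood comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, InterpolationWarning
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.stattools import kpss

from .ingest import WeeklySeries

__all__ = [
    "SarimaSpec",
    "ForecastSeries",
    "ExcessSeries",
    "select_order",
    "forecast_expected",
    "compute_excess",
    "estimate_excess",
    "excess_frame",
]

logger = logging.getLogger(__name__)

#: STL-based seasonal strength above which one seasonal difference is taken
SEASONAL_STRENGTH_THRESHOLD = 0.64

MAX_P = MAX_Q = 5
MAX_SP = MAX_SQ = 2
MAX_D = 2
MAX_SD = 1
MAX_MODELS = 60


@dataclass(frozen=True)
class SarimaSpec:
    """Seasonal ARIMA order (p, d, q)(P, D, Q)_m with an optional constant."""

    p: int
    d: int
    q: int
    P: int = 0
    D: int = 0
    Q: int = 0
    m: int = 1
    include_constant: bool = False
    aicc: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if min(self.p, self.d, self.q, self.P, self.D, self.Q) < 0:
            raise ValueError("all orders must be nonnegative")
        if self.d > MAX_D or self.D > MAX_SD or self.m < 1:
            raise ValueError(f"orders out of range: d <= {MAX_D}, D <= {MAX_SD}, m >= 1")

    def __str__(self) -> str:
        c = "c" if self.include_constant else ""
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})[{self.m}]{c}"


@dataclass
class ForecastSeries:
    """Counterfactual expected volume with a 95% band."""

    expected: pd.Series
    lower95: pd.Series
    upper95: pd.Series

    def __post_init__(self) -> None:
        if not (self.lower95.index.equals(self.expected.index) and self.upper95.index.equals(self.expected.index)):
            raise ValueError("band and point-forecast indexes differ")
        if (self.lower95 > self.expected + 1e-9).any() or (self.expected > self.upper95 + 1e-9).any():
            raise ValueError("forecast band does not bracket the point forecast")

    @property
    def week_start_dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.expected.index)

    def __len__(self) -> int:
        return len(self.expected)


@dataclass
class ExcessSeries:
    """Observed minus expected weekly search volume over the pandemic window."""

    country_code: str
    term: str
    values: pd.Series  # excess, indexed by week start
    observed: pd.Series | None = None
    forecast: ForecastSeries | None = None

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# order selection
# ---------------------------------------------------------------------------

def _as_series(series) -> pd.Series:
    """Accept a WeeklySeries/ExcessSeries container or a plain Series."""
    if isinstance(series, pd.Series):
        return series
    return pd.Series(getattr(series, "values", series))


def _as_array(series) -> np.ndarray:
    return _as_series(series).to_numpy(dtype=float)


def seasonal_strength(y: np.ndarray, m: int) -> float:
    """STL-based seasonal strength: ``max(0, 1 - var(R)/var(S + R))``."""
    if m < 2 or len(y) < 2 * m:
        return 0.0
    res = STL(pd.Series(y), period=m).fit()
    denom = np.var(res.seasonal + res.resid)
    if denom == 0:
        return 0.0
    return max(0.0, 1.0 - np.var(res.resid) / denom)


def _choose_D(y: np.ndarray, m: int) -> int:
    return 1 if seasonal_strength(y, m) > SEASONAL_STRENGTH_THRESHOLD else 0


def _choose_d(y: np.ndarray, max_d: int = MAX_D, alpha: float = 0.05) -> int:
    """Successive KPSS tests: difference while level stationarity is rejected."""
    d = 0
    x = y.copy()
    while d < max_d:
        if np.allclose(x, x[0]):
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", InterpolationWarning)
            _, p_value, *_ = kpss(x, regression="c", nlags="auto")
        if p_value >= alpha:
            break
        x = np.diff(x)
        d += 1
    return d


def _fit_candidate(y: np.ndarray, spec: SarimaSpec):
    """Fit one candidate; returns (results, aicc) or None on failure."""
    trend = "c" if spec.include_constant else "n"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.tsa.SARIMAX(
                y,
                order=(spec.p, spec.d, spec.q),
                seasonal_order=(spec.P, spec.D, spec.Q, spec.m) if spec.m > 1 else (0, 0, 0, 0),
                trend=trend,
            )
            res = model.fit(disp=0, method="lbfgs", maxiter=200)
        aicc = float(res.info_criteria("aicc"))
        if not np.isfinite(aicc):
            return None
        return res, aicc
    except (np.linalg.LinAlgError, ValueError, IndexError) as exc:
        logger.info("candidate %s failed to fit: %s", spec, exc)
        return None


def _neighbors(spec: SarimaSpec, seasonal: bool) -> Iterable[SarimaSpec]:
    moves: list[tuple[int, int, int, int, bool]] = []
    for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)):
        moves.append((spec.p + dp, spec.q + dq, spec.P, spec.Q, spec.include_constant))
    if seasonal:
        for dP, dQ in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)):
            moves.append((spec.p, spec.q, spec.P + dP, spec.Q + dQ, spec.include_constant))
    if spec.d + spec.D <= 1:
        moves.append((spec.p, spec.q, spec.P, spec.Q, not spec.include_constant))
    for p, q, P, Q, const in moves:
        if 0 <= p <= MAX_P and 0 <= q <= MAX_Q and 0 <= P <= MAX_SP and 0 <= Q <= MAX_SQ:
            yield replace(spec, p=p, q=q, P=P, Q=Q, include_constant=const, aicc=float("nan"))


def select_order(series, m: int = 52) -> SarimaSpec:
    """Stepwise automatic sARIMA order selection on a baseline segment.

    Starts from the four standard models (2,d,2)(1,D,1), (0,d,0)(0,D,0),
    (1,d,0)(1,D,0) and (0,d,1)(0,D,1), then repeatedly moves to the best
    AICc neighbor (single-step changes of p, q, P, Q and the constant) until
    no candidate improves, visiting at most ``MAX_MODELS`` fits.
    """
    y = _as_array(series)
    if len(y) < 2 * m and m > 1:
        raise ValueError(f"baseline segment needs >= {2 * m} observations for m={m}, got {len(y)}")
    if np.var(y) == 0:
        raise ValueError("degenerate series: zero variance")
    seasonal = m > 1
    D = _choose_D(y, m) if seasonal else 0
    yd = y[m:] - y[:-m] if D else y
    d = _choose_d(yd)
    const = d + D == 0

    if seasonal:
        starts = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
    else:
        starts = [(2, 2, 0, 0), (0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0)]
    candidates = [
        SarimaSpec(p, d, q, P, D, Q, m if seasonal else 1, include_constant=const)
        for p, q, P, Q in starts
    ]

    visited: dict[tuple, float] = {}
    fit_log: list[str] = []

    def key(s: SarimaSpec):
        return (s.p, s.d, s.q, s.P, s.D, s.Q, s.include_constant)

    def evaluate(s: SarimaSpec) -> float:
        k = key(s)
        if k in visited:
            return visited[k]
        if len(visited) >= MAX_MODELS:
            return float("inf")
        out = _fit_candidate(y, s)
        if out is None:
            fit_log.append(f"{s}: fit failed")
            visited[k] = float("inf")
        else:
            visited[k] = out[1]
        return visited[k]

    best = None
    best_aicc = float("inf")
    for cand in candidates:
        a = evaluate(cand)
        if a < best_aicc:
            best, best_aicc = cand, a
    if best is None or not np.isfinite(best_aicc):
        raise RuntimeError("all candidate sARIMA fits failed:\n" + "\n".join(fit_log))

    improved = True
    while improved and len(visited) < MAX_MODELS:
        improved = False
        for cand in _neighbors(best, seasonal):
            a = evaluate(cand)
            if a < best_aicc:
                best, best_aicc = cand, a
                improved = True
                break
    return replace(best, aicc=best_aicc)


# ---------------------------------------------------------------------------
# forecasting and excess
# ---------------------------------------------------------------------------

def forecast_expected(series, spec: SarimaSpec, horizon: int) -> ForecastSeries:
    """Fit ``spec`` on the baseline segment and forecast ``horizon`` weeks
    ahead with normal-theory 95% intervals from the model forecast variance."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1 week")
    y = _as_array(series)
    out = _fit_candidate(y, spec)
    if out is None:
        raise RuntimeError(f"sARIMA fit failed for spec {spec}")
    res, _ = out
    fc = res.get_forecast(steps=horizon)
    mean = np.asarray(fc.predicted_mean)
    conf = np.asarray(fc.conf_int(alpha=0.05))
    values = _as_series(series)
    if isinstance(values.index, pd.DatetimeIndex):
        step = values.index[-1] - values.index[-2] if len(values) > 1 else pd.Timedelta(days=7)
        idx = pd.date_range(values.index[-1] + step, periods=horizon, freq=step)
    else:
        idx = pd.RangeIndex(len(y), len(y) + horizon)
    return ForecastSeries(
        expected=pd.Series(mean, index=idx),
        lower95=pd.Series(conf[:, 0], index=idx),
        upper95=pd.Series(conf[:, 1], index=idx),
    )


def compute_excess(observed, forecast: ForecastSeries, country_code: str = "", term: str = "insomnia") -> ExcessSeries:
    """Weekly excess: observed minus expected, no clipping."""
    obs = _as_series(observed)
    if not obs.index.equals(forecast.expected.index):
        diff = obs.index.symmetric_difference(forecast.expected.index)
        first = diff[0] if len(diff) else "?"
        raise ValueError(f"observed and forecast dates differ; first mismatch: {first}")
    code = getattr(observed, "country_code", country_code)
    term_ = getattr(observed, "term", term)
    return ExcessSeries(
        country_code=code,
        term=term_,
        values=obs - forecast.expected,
        observed=obs,
        forecast=forecast,
    )


def estimate_excess(
    series: WeeklySeries,
    baseline_end: str | pd.Timestamp,
    pandemic_start: str | pd.Timestamp,
    pandemic_end: str | pd.Timestamp | None = None,
    m: int = 52,
    spec: SarimaSpec | None = None,
) -> ExcessSeries:
    """Full per-series pipeline: order selection on the baseline window,
    counterfactual forecast over the pandemic window, excess computation."""
    baseline = series.values.loc[: pd.Timestamp(baseline_end)]
    end = pd.Timestamp(pandemic_end) if pandemic_end is not None else None
    observed = series.values.loc[pd.Timestamp(pandemic_start): end]
    if spec is None:
        spec = select_order(baseline, m=m)
    forecast = forecast_expected(baseline, spec, horizon=len(observed))
    if not observed.index.equals(forecast.expected.index):
        forecast = ForecastSeries(
            expected=pd.Series(forecast.expected.to_numpy(), index=observed.index),
            lower95=pd.Series(forecast.lower95.to_numpy(), index=observed.index),
            upper95=pd.Series(forecast.upper95.to_numpy(), index=observed.index),
        )
    return compute_excess(
        pd.Series(observed), forecast, country_code=series.country_code, term=series.term
    )


def excess_frame(excess: ExcessSeries) -> pd.DataFrame:
    """Tidy one-row-per-week frame (the serialization schema)."""
    df = pd.DataFrame({"week_start": excess.values.index, "excess": excess.values.to_numpy()})
    df.insert(0, "term", excess.term)
    df.insert(0, "country", excess.country_code)
    if excess.observed is not None:
        df["observed"] = excess.observed.to_numpy()
    if excess.forecast is not None:
        df["expected"] = excess.forecast.expected.to_numpy()
        df["lower95"] = excess.forecast.lower95.to_numpy()
        df["upper95"] = excess.forecast.upper95.to_numpy()
    return df
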