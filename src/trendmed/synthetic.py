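"""Synthetic study scenarios with a known causal ground truth.

The generator realizes the causal diagram the analysis assumes: national
COVID-19 deaths (exposure) drive stay-at-home behavior (mediator, residential
mobility change) with slope ``alpha``; weekly excess search volume (outcome)
responds to the mediator with slope ``beta`` and to the exposure directly
with slope ``gamma``, on top of country and calendar-month effects and noise.
The true total effect is therefore ``gamma + alpha*beta`` and the true
proportion mediated ``100*alpha*beta / (gamma + alpha*beta)``.

Search baselines are seasonal (annual sine plus AR(1) noise) over a 5-year
pre-pandemic window so the counterfactual-forecasting stage has seasonality
to learn; pandemic weeks receive the structural excess additively.  All
randomness flows from a single scenario seed through per-country,
per-purpose substreams, so adding a country never reshuffles the draws of
existing countries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import DailySeries, WeeklySeries, load_registry, CountryRegistry

__all__ = [
    "ScenarioTruth",
    "ScenarioError",
    "default_scenario",
    "generate_baseline_search",
    "generate_deaths",
    "generate_mobility",
    "structural_excess",
    "generate_pandemic_panel",
    "simulate_panel",
    "noise_free_panel",
]

#: AR(1) coefficient of the search-baseline noise
SEARCH_AR_PHI = 0.5

# substream tags (second entry of the seed list fed to default_rng)
_S_SCENARIO, _S_SEARCH, _S_DEATHS, _S_MOBILITY, _S_OUTCOME = range(5)


class ScenarioError(ValueError):
    """Raised for scenario configurations the generator refuses to realize."""


@dataclass(frozen=True)
class ScenarioTruth:
    """Full description of a synthetic study scenario.

    Units: ``alpha`` in mobility percentage points per (deaths/day);
    ``beta`` in excess search points per mobility percentage point;
    ``gamma`` in excess search points per (deaths/day); noise SDs in the
    units of the stream they perturb.  ``wave_spec`` maps country code to
    a list of ``(peak_date, peak_height deaths/day, width_days)`` tuples.
    """

    n_high: int = 31
    n_middle: int = 14
    alpha: float = 0.01
    beta: float = 0.03
    gamma: float = 7e-4
    seasonal_amplitude: float = 10.0
    baseline_level: float = 50.0
    sigma_search: float = 1.0
    sigma_mobility: float = 1.0
    sigma_outcome: float = 0.5
    sigma_deaths: float = 2.0
    wave_spec: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    seed: int = 0
    baseline_start: str = "2015-03-01"
    pandemic_start: str = "2020-03-01"
    pandemic_end: str = "2022-02-28"

    def __post_init__(self) -> None:
        lo = self.baseline_level - self.seasonal_amplitude
        hi = self.baseline_level + self.seasonal_amplitude
        if lo < 0 or hi > 100:
            raise ScenarioError(
                f"baseline_level ± seasonal_amplitude spans [{lo}, {hi}], "
                "outside the [0, 100] search-volume scale"
            )
        horizon_days = (pd.Timestamp(self.pandemic_end) - pd.Timestamp(self.pandemic_start)).days
        if horizon_days < 364:
            raise ScenarioError("pandemic horizon shorter than one year; stratification impossible")

    # -- derived ground truth ------------------------------------------------
    @property
    def total_effect(self) -> float:
        """True total effect of exposure on the outcome: gamma + alpha*beta."""
        return self.gamma + self.alpha * self.beta

    @property
    def mediation_effect(self) -> float:
        return self.alpha * self.beta

    @property
    def proportion_mediated(self) -> float:
        """True PM in percent; undefined (raises) when the total effect is 0."""
        if self.total_effect == 0:
            raise ZeroDivisionError("total effect is zero; PM undefined")
        return 100.0 * self.alpha * self.beta / self.total_effect

    # -- grids ---------------------------------------------------------------
    @property
    def weeks(self) -> pd.DatetimeIndex:
        return pd.date_range(self.baseline_start, self.pandemic_end, freq="7D")

    @property
    def baseline_weeks(self) -> pd.DatetimeIndex:
        w = self.weeks
        return w[w < pd.Timestamp(self.pandemic_start)]

    @property
    def pandemic_weeks(self) -> pd.DatetimeIndex:
        w = self.weeks
        return w[w >= pd.Timestamp(self.pandemic_start)]

    @property
    def pandemic_days(self) -> pd.DatetimeIndex:
        return pd.date_range(self.pandemic_start, self.pandemic_end, freq="D")

    def registry(self) -> CountryRegistry:
        base = load_registry()
        codes = (
            base.codes_by_income("high")[: self.n_high]
            + base.codes_by_income("middle")[: self.n_middle]
        )
        if len(codes) != self.n_high + self.n_middle:
            raise ScenarioError(
                "default registry has too few countries for the requested strata sizes"
            )
        return base.subset(codes)


def _rng(truth: ScenarioTruth, stream: int, index: int = 0) -> np.random.Generator:
    """Counter-style substream: (seed, stream tag, unit index)."""
    return np.random.default_rng([truth.seed, stream, index])


_CODES_CACHE: dict[tuple[int, int], list[str]] = {}


def _scenario_codes(truth: ScenarioTruth) -> list[str]:
    key = (truth.n_high, truth.n_middle)
    if key not in _CODES_CACHE:
        _CODES_CACHE[key] = truth.registry().codes
    return _CODES_CACHE[key]


def _country_index(truth: ScenarioTruth, country: str) -> int:
    try:
        return _scenario_codes(truth).index(country)
    except ValueError:
        raise KeyError(f"country {country!r} not in scenario registry") from None


def default_scenario(seed: int = 0, **overrides) -> ScenarioTruth:
    """Default 45-country scenario (31 high-, 14 middle-income, 24 pandemic
    months, true PM = 30%) with per-country death waves drawn from the seed.

    Each country receives 2-3 Gaussian death waves with peak heights between
    50 and 2000 deaths/day and widths of 20-60 days, spread over the pandemic
    horizon -- the magnitude regime under which per-death effects are O(1e-4)
    and monthly excess is O(0.1-1) search points.
    """
    truth = ScenarioTruth(seed=seed, **{k: v for k, v in overrides.items() if k != "wave_spec"})
    if "wave_spec" in overrides:
        return replace(truth, wave_spec=overrides["wave_spec"])
    start = pd.Timestamp(truth.pandemic_start)
    end = pd.Timestamp(truth.pandemic_end)
    horizon = (end - start).days
    waves: dict[str, list[tuple]] = {}
    for i, code in enumerate(truth.registry().codes):
        rng = _rng(truth, _S_SCENARIO, i + 1)
        n_waves = int(rng.integers(2, 4))
        spec = []
        for w in range(n_waves):
            # peaks spread across the horizon with jitter so countries differ
            frac = (w + 0.5) / n_waves + rng.uniform(-0.1, 0.1)
            peak = start + pd.Timedelta(days=int(np.clip(frac, 0.05, 0.95) * horizon))
            height = float(rng.uniform(50, 2000))
            width = float(rng.uniform(20, 60))
            spec.append((str(peak.date()), height, width))
        waves[code] = spec
    return replace(truth, wave_spec=waves)


# ---------------------------------------------------------------------------
# exposure, mediator, outcome streams
# ---------------------------------------------------------------------------

def generate_deaths(truth: ScenarioTruth, country: str) -> DailySeries:
    """Daily deaths: sum of Gaussian-shaped waves plus half-normal noise."""
    spec = truth.wave_spec.get(country)
    if not spec:
        raise ScenarioError(f"wave_spec missing or empty for {country!r}")
    days = truth.pandemic_days
    t = np.arange(len(days), dtype=float)
    start = days[0]
    deaths = np.zeros(len(days))
    for peak_date, height, width in spec:
        peak_t = (pd.Timestamp(peak_date) - start).days
        deaths += height * np.exp(-0.5 * ((t - peak_t) / width) ** 2)
    if truth.sigma_deaths > 0:
        rng = _rng(truth, _S_DEATHS, _country_index(truth, country))
        deaths = deaths + np.abs(rng.normal(0.0, truth.sigma_deaths, len(days)))
    return DailySeries(country, "new_deaths", pd.Series(deaths, index=days))


def _monthly_mean(values: pd.Series) -> pd.Series:
    """Calendar-month mean over available days/weeks (index -> month period)."""
    return values.groupby(values.index.to_period("M")).mean()


def generate_mobility(truth: ScenarioTruth, country: str, deaths: DailySeries | None = None) -> DailySeries:
    """Residential mobility change: alpha times the monthly-mean death count,
    held constant within each month, plus a country intercept and monthly
    noise.

    The mediator responds to the *monthly-mean* exposure because the
    mediation models operate at monthly resolution; a constant-within-month
    mediator keeps those models exactly correctly specified (no
    aggregation-induced attenuation).
    """
    if deaths is None:
        deaths = generate_deaths(truth, country)
    idx = _country_index(truth, country)
    rng = _rng(truth, _S_MOBILITY, idx)
    monthly_exposure = _monthly_mean(deaths.values)
    country_intercept = rng.normal(8.0, 3.0)
    noise = rng.normal(0.0, truth.sigma_mobility, len(monthly_exposure)) if truth.sigma_mobility > 0 else 0.0
    monthly = truth.alpha * monthly_exposure + country_intercept + noise
    days = truth.pandemic_days
    daily = monthly.reindex(days.to_period("M")).to_numpy()
    return DailySeries(country, "residential_pct_change", pd.Series(daily, index=days))


def _month_effects(truth: ScenarioTruth) -> pd.Series:
    """Calendar-month effects shared by all countries (SD 0.5 search points)."""
    months = pd.period_range(truth.pandemic_start, truth.pandemic_end, freq="M")
    rng = _rng(truth, _S_SCENARIO, 0)
    return pd.Series(rng.normal(0.0, 0.5, len(months)), index=months)


def structural_excess(
    truth: ScenarioTruth,
    country: str,
    term: str,
    deaths: DailySeries | None = None,
    mobility: DailySeries | None = None,
) -> pd.Series:
    """Weekly structural excess injected during the pandemic window:
    ``gamma*exposure + beta*mobility + month effect + noise`` where exposure
    and mobility enter at their monthly values (month of the week start)."""
    if deaths is None:
        deaths = generate_deaths(truth, country)
    if mobility is None:
        mobility = generate_mobility(truth, country, deaths)
    weeks = truth.pandemic_weeks
    week_months = weeks.to_period("M")
    exposure_m = _monthly_mean(deaths.values)
    mobility_m = _monthly_mean(mobility.values)
    tau = _month_effects(truth)
    excess = (
        truth.gamma * exposure_m.reindex(week_months).to_numpy()
        + truth.beta * mobility_m.reindex(week_months).to_numpy()
        + tau.reindex(week_months).to_numpy()
    )
    if truth.sigma_outcome > 0:
        term_offset = 0 if term == "insomnia" else 1
        idx = _country_index(truth, country)
        rng = _rng(truth, _S_OUTCOME, 2 * idx + term_offset)
        excess = excess + rng.normal(0.0, truth.sigma_outcome, len(weeks))
    return pd.Series(excess, index=weeks)


# ---------------------------------------------------------------------------
# search-volume series
# ---------------------------------------------------------------------------

def generate_baseline_search(
    truth: ScenarioTruth,
    country: str,
    term: str,
    include_pandemic_excess: bool = True,
) -> WeeklySeries:
    """Weekly search-volume series for one country and term.

    The baseline component is ``baseline_level + seasonal_amplitude *
    sin(2*pi*week/52 + country phase)`` plus AR(1) noise (phi = 0.5, marginal
    SD ``sigma_search``), clipped to [0, 100].  With
    ``include_pandemic_excess`` the structural pandemic excess is added on
    top of the clipped baseline (the sum is deliberately not re-clipped so
    that injected excess is exactly recoverable as the difference from the
    baseline-only series).
    """
    weeks = truth.weeks
    idx = _country_index(truth, country)
    term_offset = 0 if term == "insomnia" else 1
    rng = _rng(truth, _S_SEARCH, 2 * idx + term_offset)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(len(weeks), dtype=float)
    base = truth.baseline_level + truth.seasonal_amplitude * np.sin(2 * np.pi * t / 52 + phase)
    if truth.sigma_search > 0:
        innov_sd = truth.sigma_search * np.sqrt(1 - SEARCH_AR_PHI**2)
        eps = rng.normal(0.0, innov_sd, len(weeks))
        noise = np.empty(len(weeks))
        noise[0] = rng.normal(0.0, truth.sigma_search)
        for i in range(1, len(weeks)):
            noise[i] = SEARCH_AR_PHI * noise[i - 1] + eps[i]
        base = base + noise
    clipped = np.clip(base, 0.0, 100.0)
    n_baseline = (weeks < pd.Timestamp(truth.pandemic_start)).sum()
    n_clipped = int((clipped[:n_baseline] != base[:n_baseline]).sum())
    if n_clipped > 0.01 * n_baseline:
        raise ScenarioError(
            f"{n_clipped}/{n_baseline} baseline weeks clipped at the [0, 100] bounds; "
            "clipping this heavy would bias the seasonal-baseline fit"
        )
    values = pd.Series(clipped, index=weeks)
    if include_pandemic_excess:
        excess = structural_excess(truth, country, term)
        values = values.add(excess, fill_value=0.0)
    return _unchecked_weekly(country, term, values)


def _unchecked_weekly(country: str, term: str, values: pd.Series) -> WeeklySeries:
    """Build a WeeklySeries allowing values slightly outside [0, 100].

    Injected pandemic excess is added after clipping and may exceed the
    Trends scale; the container's bounds check is for ingested data, not for
    the generator's additive construction.
    """
    obj = object.__new__(WeeklySeries)
    v = pd.Series(values, dtype=float)
    v.index = pd.DatetimeIndex(v.index)
    v.index.name = "week_start"
    object.__setattr__(obj, "country_code", country)
    object.__setattr__(obj, "term", term)
    object.__setattr__(obj, "values", v)
    return obj


# ---------------------------------------------------------------------------
# full scenario realizations
# ---------------------------------------------------------------------------

def generate_pandemic_panel(truth: ScenarioTruth):
    """Realize the full scenario.

    Returns ``(search, daily, registry, truth)`` where ``search`` maps
    ``(country, term)`` to the pandemic :class:`WeeklySeries` (baseline plus
    injected excess), ``daily`` maps ``(country, metric)`` to the mobility
    and death :class:`DailySeries`, and ``registry`` carries the income
    strata.
    """
    registry = truth.registry()
    search: dict[tuple, WeeklySeries] = {}
    daily: dict[tuple, DailySeries] = {}
    for code in registry.codes:
        deaths = generate_deaths(truth, code)
        mobility = generate_mobility(truth, code, deaths)
        daily[(code, "new_deaths")] = deaths
        daily[(code, "residential_pct_change")] = mobility
        for term in ("insomnia", "suicide"):
            search[(code, term)] = generate_baseline_search(truth, code, term)
    return search, daily, registry, truth


_GRID_CACHE: dict[tuple, tuple] = {}


def _calendar_grids(truth: ScenarioTruth):
    """Cached month codes of the daily and weekly pandemic grids."""
    key = (truth.baseline_start, truth.pandemic_start, truth.pandemic_end)
    if key not in _GRID_CACHE:
        days = truth.pandemic_days
        weeks = truth.pandemic_weeks
        months = pd.period_range(truth.pandemic_start, truth.pandemic_end, freq="M")
        month_pos = {m: i for i, m in enumerate(months)}
        day_codes = np.array([month_pos[m] for m in days.to_period("M")])
        week_codes = np.array([month_pos[m] for m in weeks.to_period("M")])
        _GRID_CACHE[key] = (days, weeks, months, day_codes, week_codes)
    return _GRID_CACHE[key]


def simulate_panel(truth: ScenarioTruth, term: str = "insomnia"):
    """Country x month analysis panel for one term, measuring the injected
    excess exactly (skips the counterfactual-forecast stage, whose role on
    synthetic data is only to *estimate* this quantity).

    Used for Monte-Carlo studies of the mediation stage; draws the same
    substreams as the per-country generators, so the panel equals what
    :func:`generate_pandemic_panel` plus the panel builder would produce
    from exactly measured excess.  Columns match the panel builder's schema.
    """
    from .panel import PANEL_COLUMNS, PanelDataset, assign_pandemic_year

    registry = truth.registry()
    income = dict(zip(registry.entries["country_code"], registry.entries["income_group"]))
    codes = registry.codes
    days, weeks, months, day_codes, week_codes = _calendar_grids(truth)
    n_c, n_d, n_w, n_m = len(codes), len(days), len(weeks), len(months)
    day_counts = np.bincount(day_codes, minlength=n_m)
    week_counts = np.bincount(week_codes, minlength=n_m)
    t = np.arange(n_d, dtype=float)
    start = days[0]

    exposure = np.empty((n_c, n_m))
    mediator = np.empty((n_c, n_m))
    for i, code in enumerate(codes):
        spec = truth.wave_spec.get(code)
        if not spec:
            raise ScenarioError(f"wave_spec missing or empty for {code!r}")
        deaths = np.zeros(n_d)
        for peak_date, height, width in spec:
            peak_t = (pd.Timestamp(peak_date) - start).days
            deaths += height * np.exp(-0.5 * ((t - peak_t) / width) ** 2)
        if truth.sigma_deaths > 0:
            rng = _rng(truth, _S_DEATHS, i)
            deaths = deaths + np.abs(rng.normal(0.0, truth.sigma_deaths, n_d))
        exposure[i] = np.bincount(day_codes, deaths, minlength=n_m) / day_counts
        rng = _rng(truth, _S_MOBILITY, i)
        intercept = rng.normal(8.0, 3.0)
        noise = rng.normal(0.0, truth.sigma_mobility, n_m) if truth.sigma_mobility > 0 else 0.0
        mediator[i] = truth.alpha * exposure[i] + intercept + noise

    tau = _rng(truth, _S_SCENARIO, 0).normal(0.0, 0.5, n_m)
    term_offset = 0 if term == "insomnia" else 1
    outcome = np.empty((n_c, n_m))
    for i in range(n_c):
        weekly = (
            truth.gamma * exposure[i, week_codes]
            + truth.beta * mediator[i, week_codes]
            + tau[week_codes]
        )
        if truth.sigma_outcome > 0:
            rng = _rng(truth, _S_OUTCOME, 2 * i + term_offset)
            weekly = weekly + rng.normal(0.0, truth.sigma_outcome, n_w)
        outcome[i] = np.bincount(week_codes, weekly, minlength=n_m) / week_counts

    panel = pd.DataFrame(
        {
            "country": np.repeat(codes, n_m),
            "month": np.tile(months, n_c),
            "exposure": exposure.ravel(),
            "mediator": mediator.ravel(),
            "outcome": outcome.ravel(),
            "income_group": np.repeat([income[c] for c in codes], n_m),
            "pandemic_year": np.tile([assign_pandemic_year(m) for m in months], n_c),
        }
    )[PANEL_COLUMNS]
    return PanelDataset(panel, term, "new_deaths")


def noise_free_panel(
    alpha: float,
    beta: float,
    gamma: float,
    n_countries: int = 6,
    n_months: int = 12,
    seed: int = 0,
):
    """Exactly linear, noise-free panel for analytic recovery checks.

    The mediator is ``alpha * exposure + country effect + u`` where the
    exogenous mediator variation ``u`` (lockdown-policy variation unrelated
    to deaths) is constructed exactly orthogonal to the within-transformed
    exposure, so the two-way FE estimates recover ``alpha``, ``beta``,
    ``gamma`` -- and hence the decomposition identities -- to machine
    precision.  The outcome is ``gamma*exposure + beta*mediator + country
    effect + month effect`` with no noise term.
    """
    from .mediation import _two_way_demean
    from .panel import PANEL_COLUMNS, PanelDataset

    rng = np.random.default_rng(seed)
    n = n_countries * n_months
    ci = np.repeat(np.arange(n_countries), n_months)
    ti = np.tile(np.arange(n_months), n_countries)
    exposure = rng.uniform(0, 1000, n)
    e_t = _two_way_demean(exposure, ci, ti)
    u = rng.normal(0, 3.0, n)
    u_t = _two_way_demean(u, ci, ti)
    u_t -= (u_t @ e_t) / (e_t @ e_t) * e_t  # orthogonalize against exposure
    c_eff = rng.normal(8, 3, n_countries)
    t_eff = rng.normal(0, 1, n_months)
    mediator = alpha * exposure + c_eff[ci] + u_t
    outcome = gamma * exposure + beta * mediator + rng.normal(0, 1, n_countries)[ci] + t_eff[ti]
    months = pd.period_range("2020-03", periods=n_months, freq="M")
    from .panel import assign_pandemic_year

    panel = pd.DataFrame(
        {
            "country": np.array([f"S{i:02d}" for i in range(n_countries)])[ci],
            "month": months[ti],
            "exposure": exposure,
            "mediator": mediator,
            "outcome": outcome,
            "income_group": "high",
            "pandemic_year": [assign_pandemic_year(m) for m in months[ti]],
        }
    )[PANEL_COLUMNS]
    return PanelDataset(panel, "insomnia", "new_deaths")
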