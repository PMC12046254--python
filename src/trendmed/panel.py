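"""Country x month panel assembly.

Daily death/case counts and daily residential-mobility changes are averaged
over calendar months; weekly excess search volume is assigned to the month
containing its week-start date and averaged.  The three monthly streams are
inner-joined per country into an analysis panel with income-group and
pandemic-year strata attached -- the sole input of the mediation stage.

Pandemic years follow the study calendar: year 1 = March 2020 - February
2021, year 2 = March 2021 - February 2022, year 3 = March - October 2022
(an 8-month stratum; the mobility data release stopped in October 2022).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Union

import pandas as pd

from .ingest import DailySeries

__all__ = [
    "PanelDataset",
    "monthly_exposure",
    "monthly_mediator",
    "monthly_outcome",
    "build_rows",
    "assemble_panel",
    "assign_pandemic_year",
]

PANEL_COLUMNS = [
    "country",
    "month",
    "exposure",
    "mediator",
    "outcome",
    "income_group",
    "pandemic_year",
]

_YEAR_WINDOWS = {
    1: (pd.Period("2020-03", "M"), pd.Period("2021-02", "M")),
    2: (pd.Period("2021-03", "M"), pd.Period("2022-02", "M")),
    3: (pd.Period("2022-03", "M"), pd.Period("2022-10", "M")),
}


def assign_pandemic_year(month: pd.Period) -> float:
    """Study-calendar pandemic year of a month (1, 2, 3, or NaN outside)."""
    for year, (lo, hi) in _YEAR_WINDOWS.items():
        if lo <= month <= hi:
            return year
    return float("nan")


def _monthly_mean_daily(series: DailySeries) -> pd.Series:
    v = series.values
    out = v.groupby(v.index.to_period("M")).mean()
    out.index.name = "month"
    return out


def monthly_exposure(deaths: DailySeries) -> pd.Series:
    """Mean daily death (or case) count per calendar month.

    Months with no coverage are simply absent; partially covered months use
    the mean over available days.
    """
    return _monthly_mean_daily(deaths)


def monthly_mediator(mobility: DailySeries) -> pd.Series:
    """Mean residential %-change per calendar month."""
    return _monthly_mean_daily(mobility)


def monthly_outcome(excess) -> pd.Series:
    """Mean weekly excess per calendar month.

    Accepts an :class:`~trendmed.excess.ExcessSeries` or a plain Series
    indexed by week-start dates.  Each week belongs to the month containing
    its start date (a week starting Feb 27 counts toward February even
    though it spans into March).
    """
    v = excess if isinstance(excess, pd.Series) else pd.Series(getattr(excess, "values", excess))
    out = v.groupby(pd.DatetimeIndex(v.index).to_period("M")).mean()
    out.index.name = "month"
    return out


def build_rows(
    country_code: str,
    exposure: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    income_group: str,
) -> pd.DataFrame:
    """Inner-join the three monthly streams of one country into panel rows."""
    df = pd.concat(
        {"exposure": exposure, "mediator": mediator, "outcome": outcome}, axis=1, join="inner"
    ).dropna()
    df.index.name = "month"
    df = df.reset_index()
    df.insert(0, "country", country_code)
    df["income_group"] = income_group
    df["pandemic_year"] = [assign_pandemic_year(m) for m in df["month"]]
    return df[PANEL_COLUMNS]


@dataclass
class PanelDataset:
    """Analysis-ready country x month panel for one term and exposure metric."""

    data: pd.DataFrame
    term: str
    exposure_metric: str = "new_deaths"

    def __post_init__(self) -> None:
        df = self.data
        missing = set(PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        if df.duplicated(subset=["country", "month"]).any():
            raise ValueError("duplicate (country, month) rows in panel")
        counts = df.groupby("country").size()
        thin = counts[counts < 2].index.tolist()
        if thin:
            warnings.warn(f"dropping countries with < 2 months of data: {thin}", stacklevel=2)
            df = df[~df["country"].isin(thin)]
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    def stratum(self, income_group: str | None = None, pandemic_year: int | None = None) -> "PanelDataset":
        df = self.data
        if income_group is not None:
            df = df[df["income_group"] == income_group]
        if pandemic_year is not None:
            df = df[df["pandemic_year"] == pandemic_year]
        return PanelDataset(df.copy(), self.term, self.exposure_metric)

    def strata(self):
        """Iterate ``(income_group, pandemic_year, PanelDataset)`` over the
        non-empty strata present in the panel."""
        df = self.data.dropna(subset=["pandemic_year"])
        for (inc, yr), sub in df.groupby(["income_group", "pandemic_year"], sort=True):
            yield inc, int(yr), PanelDataset(sub.copy(), self.term, self.exposure_metric)

    # -- serialization -------------------------------------------------------
    def to_csv(self, target: Union[str, Path, IO[str]]) -> None:
        df = self.data.copy()
        df["month"] = df["month"].astype(str)
        df["term"] = self.term
        df["exposure_metric"] = self.exposure_metric
        if isinstance(target, (str, Path)):
            df.to_csv(target, index=False, lineterminator="\n")
        else:
            df.to_csv(target, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, source: Union[str, Path, IO[str]]) -> "PanelDataset":
        df = pd.read_csv(source)
        term = df["term"].iloc[0] if "term" in df.columns else "insomnia"
        metric = df["exposure_metric"].iloc[0] if "exposure_metric" in df.columns else "new_deaths"
        df = df.drop(columns=[c for c in ("term", "exposure_metric") if c in df.columns])
        df["month"] = pd.PeriodIndex(df["month"], freq="M")
        return cls(df, term, metric)


def assemble_panel(
    registry,
    excess_by_country: Mapping[str, object],
    mobility_by_country: Mapping[str, DailySeries],
    exposure_by_country: Mapping[str, DailySeries],
    term: str,
    exposure_metric: str = "new_deaths",
    income_group: str | None = None,
    pandemic_year: int | None = None,
) -> PanelDataset:
    """Build the full analysis panel from per-country streams.

    Rows are the inner join of exposure, mediator and outcome months per
    country; countries missing any stream entirely are excluded with a
    warning; month-level missingness is handled by listwise deletion.
    Optional ``income_group`` / ``pandemic_year`` filters restrict to a
    stratum.
    """
    frames = []
    skipped = []
    dropped_rows = 0
    income = dict(zip(registry.entries["country_code"], registry.entries["income_group"]))
    for code in registry.codes:
        if code not in excess_by_country or code not in mobility_by_country or code not in exposure_by_country:
            skipped.append(code)
            continue
        rows = build_rows(
            code,
            monthly_exposure(exposure_by_country[code]),
            monthly_mediator(mobility_by_country[code]),
            monthly_outcome(excess_by_country[code]),
            income[code],
        )
        n_months = max(
            len(monthly_exposure(exposure_by_country[code])),
            len(monthly_outcome(excess_by_country[code])),
        )
        dropped_rows += n_months - len(rows)
        frames.append(rows)
    if skipped:
        warnings.warn(f"countries missing a data stream, excluded: {skipped}", stacklevel=2)
    if dropped_rows:
        warnings.warn(f"{dropped_rows} country-months dropped by the inner join", stacklevel=2)
    if not frames:
        sizes = {
            "excess": len(excess_by_country),
            "mobility": len(mobility_by_country),
            "exposure": len(exposure_by_country),
        }
        emptiest = min(sizes, key=sizes.get)
        raise ValueError(f"panel empty after join; emptiest input: {emptiest} ({sizes})")
    df = pd.concat(frames, ignore_index=True)
    panel = PanelDataset(df, term, exposure_metric)
    if income_group is not None or pandemic_year is not None:
        panel = panel.stratum(income_group, pandemic_year)
        if len(panel) == 0:
            raise ValueError("requested stratum is empty")
    return panel
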