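"""Readers and writers for the three input data streams.

The pipeline consumes three public-data dialects:

* weekly relative search volumes (Google-Trends-style exports, values 0-100),
* daily residential-mobility percent change from a pre-pandemic baseline
  (Community-Mobility-Reports-style long CSV),
* daily COVID-19 death / confirmed-case counts (long CSV as in public
  JHU/OWID extracts),

plus a country registry carrying the income-group stratification and the
local-language search keywords.  Everything is validated on construction so
downstream stages can assume clean, ordered series.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

import pandas as pd

__all__ = [
    "WeeklySeries",
    "DailySeries",
    "CountryRegistry",
    "read_trends_csv",
    "write_trends_csv",
    "read_mobility_csv",
    "read_deaths_csv",
    "write_daily_csv",
    "load_registry",
]

Source = Union[str, Path, IO[str]]

TERMS = ("insomnia", "suicide")
DAILY_METRICS = ("residential_pct_change", "new_deaths", "new_cases")
INCOME_GROUPS = ("high", "middle")

#: value substituted for censored "<1" cells in Trends exports
CENSORED_VALUE = 0.5


class DataFormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class WeeklySeries:
    """One country-term weekly relative search-volume series (0-100 scale).

    ``values`` is a float Series indexed by week-start dates, strictly
    increasing and 7 days apart.  Multi-week gaps raise a warning (they are
    flagged, never silently filled); non-weekly spacing is an error.
    """

    country_code: str
    term: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.term not in TERMS:
            raise ValueError(f"unknown term {self.term!r}; expected one of {TERMS}")
        v = pd.Series(self.values, dtype=float)
        v.index = pd.DatetimeIndex(v.index)
        v.index.name = "week_start"
        if len(v) == 0:
            raise DataFormatError("no data rows")
        deltas = v.index.to_series().diff().dropna().dt.days
        if (deltas <= 0).any():
            bad = v.index[1:][(deltas <= 0).to_numpy()][0]
            raise DataFormatError(f"week_start dates not strictly increasing at {bad.date()}")
        if (deltas % 7 != 0).any():
            bad = v.index[1:][(deltas % 7 != 0).to_numpy()][0]
            raise DataFormatError(f"non-weekly date spacing before {bad.date()}")
        if (deltas > 7).any():
            n_gaps = int((deltas > 7).sum())
            warnings.warn(
                f"{self.country_code}/{self.term}: {n_gaps} gap(s) in weekly series",
                stacklevel=2,
            )
        if (v < 0).any() or (v > 100).any():
            bad = v[(v < 0) | (v > 100)].index[0]
            raise DataFormatError(f"search volume outside [0, 100] at {bad.date()}")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def window(self, start=None, end=None) -> "WeeklySeries":
        """Sub-series of weeks with start <= week_start <= end (inclusive)."""
        return WeeklySeries(self.country_code, self.term, self.values.loc[start:end])


@dataclass
class DailySeries:
    """Per-country daily series: residential mobility change or epi counts.

    Mobility is in percentage points relative to the Jan 3 - Feb 6 2020
    baseline and may be negative.  Death counts may also be negative on
    isolated days (reporting corrections); these are kept and flagged.
    """

    country_code: str
    metric: str
    values: pd.Series

    def __post_init__(self) -> None:
        if self.metric not in DAILY_METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; expected one of {DAILY_METRICS}"
            )
        v = pd.Series(self.values, dtype=float)
        v.index = pd.DatetimeIndex(v.index)
        v.index.name = "date"
        if not v.index.is_monotonic_increasing or v.index.has_duplicates:
            raise DataFormatError(
                f"{self.country_code}/{self.metric}: dates must be strictly increasing"
            )
        if self.metric in ("new_deaths", "new_cases") and (v < 0).any():
            warnings.warn(
                f"{self.country_code}/{self.metric}: negative daily counts retained "
                f"({int((v < 0).sum())} day(s); treated as reporting corrections)",
                stacklevel=2,
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CountryRegistry:
    """Country roster with income-group labels and translated keywords."""

    entries: pd.DataFrame = field(repr=False)

    REQUIRED = ("country_code", "name", "income_group", "keyword_insomnia", "keyword_suicide")

    def __post_init__(self) -> None:
        df = self.entries
        missing = set(self.REQUIRED) - set(df.columns)
        if missing:
            raise DataFormatError(f"registry missing columns: {sorted(missing)}")
        bad = set(df["income_group"]) - set(INCOME_GROUPS)
        if bad:
            raise DataFormatError(
                f"unknown income label(s) {sorted(bad)}; expected {INCOME_GROUPS}"
            )
        if df["country_code"].duplicated().any():
            raise DataFormatError("duplicate country codes in registry")
        object.__setattr__(self, "entries", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> list[str]:
        return list(self.entries["country_code"])

    def codes_by_income(self, income_group: str) -> list[str]:
        if income_group not in INCOME_GROUPS:
            raise ValueError(f"unknown income group {income_group!r}")
        sel = self.entries["income_group"] == income_group
        return list(self.entries.loc[sel, "country_code"])

    def income_of(self, country_code: str) -> str:
        row = self.entries[self.entries["country_code"] == country_code]
        if row.empty:
            raise KeyError(country_code)
        return row["income_group"].iloc[0]

    def keyword(self, country_code: str, term: str) -> str:
        row = self.entries[self.entries["country_code"] == country_code]
        if row.empty:
            raise KeyError(country_code)
        return row[f"keyword_{term}"].iloc[0]

    def subset(self, codes: Iterable[str]) -> "CountryRegistry":
        codes = list(codes)
        df = self.entries[self.entries["country_code"].isin(codes)]
        return CountryRegistry(df.copy())


def _open(source: Source):
    """Return (stream, needs_close) for a path or an open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_trends_csv(source: Source, country_code: str = "", term: str = "insomnia") -> WeeklySeries:
    """Parse a Trends-style weekly export into a :class:`WeeklySeries`.

    The dialect allows arbitrary metadata lines before the header; the body
    is ``week,value`` rows.  Censored ``<1`` cells become 0.5 (midpoint
    imputation, unbiased under a uniform censoring model and preserving the
    [0, 100] invariant).
    """
    stream, needs_close = _open(source)
    try:
        rows: list[tuple[pd.Timestamp, float]] = []
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or "," not in line:
                continue
            date_str, _, value_str = line.partition(",")
            try:
                date = pd.Timestamp(date_str.strip())
            except ValueError:
                continue  # metadata or header line
            value_str = value_str.strip()
            value = CENSORED_VALUE if value_str == "<1" else float(value_str)
            if not 0 <= value <= 100:
                raise DataFormatError(
                    f"row {lineno}: search volume {value} outside [0, 100]"
                )
            rows.append((date, value))
        if not rows:
            raise DataFormatError("no data rows")
        values = pd.Series([v for _, v in rows], index=[d for d, _ in rows])
        return WeeklySeries(country_code, term, values)
    finally:
        if needs_close:
            stream.close()


def write_trends_csv(series: WeeklySeries, target: Source, keyword: str | None = None) -> None:
    """Write a :class:`WeeklySeries` in the Trends export dialect."""
    stream, needs_close = _open_write(target)
    try:
        label = keyword or series.term
        stream.write("Category: All categories\n\n")
        stream.write(f"Week,{label}: ({series.country_code})\n")
        for date, value in series.values.items():
            stream.write(f"{date.date()},{_fmt(value)}\n")
    finally:
        if needs_close:
            stream.close()


def _open_write(target: Source):
    if isinstance(target, (str, Path)):
        return open(target, "w", encoding="utf-8"), True
    return target, False


def _fmt(value: float) -> str:
    # .17g guarantees float round-trip through the text dialect
    return f"{value:.17g}"


def _read_long_csv(source: Source, value_col: str, country_code: str | None) -> pd.DataFrame:
    stream, needs_close = _open(source)
    try:
        df = pd.read_csv(stream)
    finally:
        if needs_close:
            stream.close()
    required = {"country", "date", value_col}
    if not required <= set(df.columns):
        raise DataFormatError(
            f"missing required column(s) {sorted(required - set(df.columns))}; "
            f"found {list(df.columns)}"
        )
    if country_code is not None:
        df = df[df["country"] == country_code]
        if df.empty:
            raise DataFormatError(f"no rows for country {country_code!r}")
    elif df["country"].nunique() > 1:
        raise DataFormatError(
            "multiple countries present; pass country_code to select one"
        )
    if df.duplicated(subset=["country", "date"]).any():
        dup = df[df.duplicated(subset=["country", "date"])].iloc[0]
        raise DataFormatError(f"duplicate (country, date) row: {dup['country']}, {dup['date']}")
    return df


def read_mobility_csv(source: Source, country_code: str | None = None) -> DailySeries:
    """Read a long-format ``country,date,residential_pct_change`` CSV."""
    df = _read_long_csv(source, "residential_pct_change", country_code)
    code = country_code or df["country"].iloc[0]
    values = pd.Series(
        df["residential_pct_change"].to_numpy(float),
        index=pd.DatetimeIndex(df["date"]),
    )
    return DailySeries(code, "residential_pct_change", values)


def read_deaths_csv(
    source: Source, metric: str = "new_deaths", country_code: str | None = None
) -> DailySeries:
    """Read a long-format ``country,date,new_deaths[,new_cases]`` CSV."""
    if metric not in ("new_deaths", "new_cases"):
        raise ValueError(f"metric must be new_deaths or new_cases, got {metric!r}")
    df = _read_long_csv(source, metric, country_code)
    code = country_code or df["country"].iloc[0]
    values = pd.Series(df[metric].to_numpy(float), index=pd.DatetimeIndex(df["date"]))
    return DailySeries(code, metric, values)


def write_daily_csv(series_list: Iterable[DailySeries], target: Source) -> None:
    """Write daily series in the long CSV dialect the readers accept.

    Mobility series produce a ``residential_pct_change`` column; epi series
    produce ``new_deaths`` / ``new_cases`` columns (merged on date when both
    metrics are present for a country).
    """
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {"country": s.country_code, "date": s.values.index.date, s.metric: s.values.to_numpy()}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df = df.groupby(["country", "date"], as_index=False, sort=True).first()
    stream, needs_close = _open_write(target)
    try:
        df.to_csv(stream, index=False, lineterminator="\n")
    finally:
        if needs_close:
            stream.close()


def load_registry(source: Source | None = None) -> CountryRegistry:
    """Load the country registry; the packaged default covers the 45-country
    study roster (31 high-income, 14 middle-income) with its translated
    insomnia/suicide keywords."""
    if source is None:
        df = _default_registry_frame().copy()
    else:
        stream, needs_close = _open(source)
        try:
            df = pd.read_csv(stream)
        finally:
            if needs_close:
                stream.close()
    return CountryRegistry(df)


_REGISTRY_CACHE: list[pd.DataFrame] = []


def _default_registry_frame() -> pd.DataFrame:
    if not _REGISTRY_CACHE:
        text = resources.files("trendmed.data").joinpath("country_registry.csv").read_text("utf-8")
        _REGISTRY_CACHE.append(pd.read_csv(io.StringIO(text)))
    return _REGISTRY_CACHE[0]
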