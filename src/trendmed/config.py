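"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    ``mode`` is ``synthetic`` (scenario parameters under ``scenario``) or
    ``files`` (paths to the three input CSVs).  The baseline window must end
    the day before the pandemic window starts.
    """

    mode: str = "synthetic"
    scenario: dict = field(default_factory=dict)
    trends_csvs: dict = field(default_factory=dict)  # {(country, term): path} as "CC:term" keys
    mobility_csv: str | None = None
    epi_csv: str | None = None
    registry_csv: str | None = None
    terms: list = field(default_factory=lambda: ["insomnia", "suicide"])
    exposure_metric: str = "new_deaths"
    baseline_start: str = "2015-03-01"
    baseline_end: str = "2020-02-29"  # leap day: last pre-pandemic day
    pandemic_start: str = "2020-03-01"
    pandemic_end: str = "2022-02-28"
    seasonal_period: int = 52
    sarima_order: list | None = None  # [p,d,q,P,D,Q]; None -> automatic selection
    outdir: str = "trendmed_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"mode must be synthetic or files, got {self.mode!r}")
        if self.exposure_metric not in ("new_deaths", "new_cases"):
            raise ValueError("exposure_metric must be new_deaths or new_cases")
        b_end = pd.Timestamp(self.baseline_end)
        p_start = pd.Timestamp(self.pandemic_start)
        if b_end >= p_start:
            raise ValueError("baseline window overlaps the pandemic window")
        if p_start - b_end != pd.Timedelta(days=1):
            raise ValueError("baseline must end the day before the pandemic window starts")
        if pd.Timestamp(self.pandemic_end) <= p_start:
            raise ValueError("pandemic window is empty")
        unknown_terms = set(self.terms) - {"insomnia", "suicide"}
        if unknown_terms:
            raise ValueError(f"unknown terms: {sorted(unknown_terms)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True, allow_unicode=True)
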