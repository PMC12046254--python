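"""Rendering of results tables and figures.

Tables follow the published layout: one block per income group, rows
{total, mediation, alternative, proportion mediated} x columns {estimate,
95% CI, p} per pandemic year.  Effect estimates print in scientific
notation with 2 significant digits; the proportion mediated prints in
percent with 1 decimal.  Plots are optional and skipped cleanly when the
matplotlib backend is unusable.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "format_estimate",
    "format_pm",
    "results_table",
    "render_results",
    "plot_country",
    "plot_trajectories",
]


def format_estimate(value: float) -> str:
    """Scientific notation with 2 significant digits (e.g. ``2.1e-04``)."""
    if pd.isna(value):
        return "NA"
    return f"{value:.1e}"


def format_pm(value: float) -> str:
    """Percent with one decimal."""
    if pd.isna(value):
        return "NA"
    return f"{value:.1f}"


def _fmt_cell(effect: str, value: float) -> str:
    return format_pm(value) if effect == "proportion_mediated" else format_estimate(value)


def results_table(table: pd.DataFrame) -> pd.DataFrame:
    """Wide formatted table: one row per (income group, effect), one column
    group per pandemic year; empty strata render as NA."""
    effects = ["total", "mediation", "alternative", "proportion_mediated"]
    years = sorted(table["pandemic_year"].dropna().unique())
    rows = []
    for inc in sorted(table["income_group"].dropna().unique()):
        for eff in effects:
            row = {"income_group": inc, "effect": eff}
            for yr in years:
                sel = table[
                    (table["income_group"] == inc)
                    & (table["pandemic_year"] == yr)
                    & (table["effect"] == eff)
                ]
                if sel.empty:
                    row[f"y{int(yr)}_estimate"] = "NA"
                    row[f"y{int(yr)}_ci"] = "NA"
                    row[f"y{int(yr)}_p"] = "NA"
                else:
                    r = sel.iloc[0]
                    row[f"y{int(yr)}_estimate"] = _fmt_cell(eff, r["estimate"])
                    row[f"y{int(yr)}_ci"] = (
                        f"{_fmt_cell(eff, r['lower95'])} to {_fmt_cell(eff, r['upper95'])}"
                    )
                    row[f"y{int(yr)}_p"] = "NA" if pd.isna(r["p"]) else f"{r['p']:.3f}"
            rows.append(row)
    return pd.DataFrame(rows)


def render_results(table: pd.DataFrame, outdir: str | Path, term: str) -> Path:
    """Write the formatted results table as text; returns the path."""
    out = Path(outdir) / f"table_{term}.txt"
    formatted = results_table(table)
    out.write_text(formatted.to_string(index=False) + "\n", encoding="utf-8")
    return out


def plot_country(excess, path: str | Path) -> Path | None:
    """Two-panel figure per country-term: observed vs expected with the 95%
    band, and the weekly excess below."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting backend absent; plots are optional
        return None
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 6), sharex=True)
    if excess.observed is not None:
        ax1.plot(excess.observed.index, excess.observed, color="tab:blue", label="observed")
    if excess.forecast is not None:
        fc = excess.forecast
        ax1.plot(fc.expected.index, fc.expected, color="black", label="expected")
        ax1.fill_between(fc.expected.index, fc.lower95, fc.upper95, color="0.8", label="95% CI")
    ax1.set_ylabel("relative search volume")
    if ax1.get_legend_handles_labels()[0]:
        ax1.legend(loc="upper left", fontsize=8)
    ax1.set_title(f"{excess.country_code}: {excess.term}")
    ax2.axhline(0.0, color="0.5", lw=0.8)
    ax2.plot(excess.values.index, excess.values, color="tab:red")
    ax2.set_ylabel("excess search volume")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)


def plot_trajectories(deaths, mobility, excess, path: str | Path) -> Path | None:
    """Triptych: daily deaths, stay-at-home measure, and weekly excess."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        return None
    fig, axes = plt.subplots(3, 1, figsize=(9, 8), sharex=True)
    axes[0].plot(deaths.values.index, deaths.values, color="0.2")
    axes[0].set_ylabel("daily deaths")
    axes[1].plot(mobility.values.index, mobility.values, color="tab:green")
    axes[1].set_ylabel("residential change (%)")
    axes[2].axhline(0.0, color="0.5", lw=0.8)
    axes[2].plot(excess.values.index, excess.values, color="tab:red")
    axes[2].set_ylabel("excess search volume")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
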