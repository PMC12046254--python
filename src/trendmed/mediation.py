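"""Panel causal mediation analysis with two-way fixed effects.

The total effect of monthly COVID-19 deaths (exposure X) on monthly excess
search volume (outcome Y) is decomposed into a part transmitted through
stay-at-home behavior (mediator M) and a remainder, using three regressions
that each absorb country and calendar-month fixed effects:

    model 1:  Y ~ X          -> theta_T (total effect)
    model 2:  Y ~ X + M      -> theta_A (alternative/direct effect), beta
    model 3:  M ~ X          -> alpha

The mediation (indirect) effect is the product of coefficients
``theta_M = alpha * beta`` with the Sobel delta-method variance
``beta^2 var(alpha) + alpha^2 var(beta)``.  In this linear, no-interaction
specification the product estimator coincides with the difference estimator
``theta_T - theta_A`` exactly, because all three regressions use the same
within-transformed data; the identity ``theta_T = theta_M + theta_A`` holds
to numerical precision on every output.

The proportion mediated is ``PM = 100 * theta_M / theta_T`` with a
delta-method variance for the ratio in which ``cov(theta_M, theta_T)`` is
approximated by ``var(theta_M)`` (from ``theta_T = theta_M + theta_A`` with
the cross-covariance of mediation and alternative parts taken as zero).  A
country-level nonparametric bootstrap is provided as an independent check on
all delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FEFit",
    "MediationEstimate",
    "fit_twoway_fe",
    "decompose",
    "proportion_mediated",
    "run_mediation",
    "mediate_stratum",
    "bootstrap_se",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class FEFit:
    """Least-squares fit after two-way (country + month) demeaning."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    df_resid: int
    r2_within: float

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov.loc[name, name]))

    def var(self, name: str) -> float:
        return float(self.cov.loc[name, name])


def _two_way_demean(
    x: np.ndarray, country_idx: np.ndarray, month_idx: np.ndarray,
    tol: float = 1e-12, max_iter: int = 500,
) -> np.ndarray:
    """Iterated within transformation (alternating projections onto the
    orthocomplements of the country and month dummy spaces)."""
    out = x.astype(float).copy()
    n_c = country_idx.max() + 1
    n_t = month_idx.max() + 1
    cnt_c = np.bincount(country_idx, minlength=n_c)
    cnt_t = np.bincount(month_idx, minlength=n_t)
    scale = max(np.abs(out).max(), 1.0)
    for _ in range(max_iter):
        mc = np.bincount(country_idx, out, minlength=n_c) / cnt_c
        out -= mc[country_idx]
        mt = np.bincount(month_idx, out, minlength=n_t) / cnt_t
        out -= mt[month_idx]
        # month means are exactly zero after the second subtraction; converged
        # once the country means have also collapsed
        resid_c = np.abs(np.bincount(country_idx, out, minlength=n_c) / cnt_c).max()
        if resid_c < tol * scale:
            break
    return out


def fit_twoway_fe(
    panel,
    outcome_var: str,
    regressors: Sequence[str],
    cluster_by_country: bool = False,
) -> FEFit:
    """Two-way fixed-effects regression of ``outcome_var`` on ``regressors``.

    Country and month intercepts are absorbed by iterated demeaning; the
    coefficient covariance is the classical OLS covariance on the
    transformed data with degrees of freedom corrected for the absorbed
    effects, or a cluster-robust (by country) sandwich when
    ``cluster_by_country`` is set.
    """
    df = getattr(panel, "data", panel)
    regressors = list(regressors)
    countries, country_idx = np.unique(df["country"].to_numpy(), return_inverse=True)
    months, month_idx = np.unique(df["month"].astype(str).to_numpy(), return_inverse=True)
    n, k = len(df), len(regressors)
    n_c, n_t = len(countries), len(months)
    if n_c < 2 or n_t < 2:
        raise ValueError(
            f"need >= 2 countries and >= 2 months for two-way fixed effects "
            f"(got {n_c} countries, {n_t} months)"
        )

    y = _two_way_demean(df[outcome_var].to_numpy(float), country_idx, month_idx)
    X = np.column_stack(
        [_two_way_demean(df[r].to_numpy(float), country_idx, month_idx) for r in regressors]
    )
    for j, r in enumerate(regressors):
        raw_scale = max(float(np.abs(df[r]).max()), 1e-30)
        if X[:, j].std() < 1e-10 * raw_scale:
            raise ValueError(
                f"regressor {r!r} has no within-variance: collinear with the fixed effects"
            )

    xtx = X.T @ X
    # scale-invariant singularity check (columns may be in unrelated units)
    norms = np.sqrt(np.diag(xtx))
    if np.linalg.cond(xtx / np.outer(norms, norms)) > 1e10:
        raise ValueError(
            f"singular design matrix for regressors {regressors} "
            "(collinear after the within transformation)"
        )
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    df_resid = n - k - (n_c - 1) - (n_t - 1) - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom after absorbing fixed effects")
    if cluster_by_country:
        meat = np.zeros((k, k))
        for c in range(n_c):
            sel = country_idx == c
            s = X[sel].T @ resid[sel]
            meat += np.outer(s, s)
        # small-sample factor as in standard CR1 cluster covariance
        adj = (n_c / (n_c - 1)) * ((n - 1) / df_resid)
        cov = adj * xtx_inv @ meat @ xtx_inv
    else:
        sigma2 = float(resid @ resid) / df_resid
        cov = sigma2 * xtx_inv
    tss = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return FEFit(
        params=pd.Series(coef, index=regressors),
        cov=pd.DataFrame(cov, index=regressors, columns=regressors),
        n_obs=n,
        df_resid=df_resid,
        r2_within=r2,
    )


def _normal_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


@dataclass
class Effect:
    """One effect estimate with normal-theory inference."""

    estimate: float
    se: float
    lower95: float = field(init=False)
    upper95: float = field(init=False)
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.lower95 = self.estimate - Z95 * self.se
        self.upper95 = self.estimate + Z95 * self.se
        # a degenerate (zero/undefined) SE yields an undefined p-value,
        # rendered as NA in tables
        self.p = _normal_p(self.estimate / self.se) if self.se > 0 else float("nan")


@dataclass
class MediationEstimate:
    """Total/mediation/alternative effects and the proportion mediated for
    one stratum -- the contract behind each results-table block."""

    total: Effect
    mediation: Effect
    alternative: Effect
    pm: Effect
    n_obs: int
    n_countries: int
    term: str | None = None
    income_group: str | None = None
    pandemic_year: int | None = None

    def to_rows(self) -> pd.DataFrame:
        rows = []
        for name, eff in [
            ("total", self.total),
            ("mediation", self.mediation),
            ("alternative", self.alternative),
            ("proportion_mediated", self.pm),
        ]:
            rows.append(
                {
                    "term": self.term,
                    "income_group": self.income_group,
                    "pandemic_year": self.pandemic_year,
                    "effect": name,
                    "estimate": eff.estimate,
                    "se": eff.se,
                    "lower95": eff.lower95,
                    "upper95": eff.upper95,
                    "p": eff.p,
                    "n_obs": self.n_obs,
                    "n_countries": self.n_countries,
                }
            )
        return pd.DataFrame(rows)


def proportion_mediated(
    theta_m: float,
    theta_t: float,
    var_m: float = 0.0,
    var_t: float = 0.0,
) -> Effect:
    """Proportion mediated ``PM = 100 * theta_m / theta_t`` (percent) with a
    delta-method standard error for the ratio.

    The variance uses ``var(PM)/PM^2 = var_m/theta_m^2 + var_t/theta_t^2 -
    2*cov/(theta_m*theta_t)`` with ``cov(theta_m, theta_t)`` approximated by
    ``var_m``; when the approximation turns the variance negative it is
    floored at zero with a warning.
    """
    if abs(theta_t) < 1e-12:
        raise ZeroDivisionError("total effect numerically zero; PM undefined")
    pm = 100.0 * theta_m / theta_t
    if theta_m == 0.0:
        # ratio delta method degenerates; fall back to var(theta_m) scaling
        var_pm = (100.0 / theta_t) ** 2 * var_m
    else:
        rel = var_m / theta_m**2 + var_t / theta_t**2 - 2.0 * var_m / (theta_m * theta_t)
        if rel < 0:
            warnings.warn(
                "delta-method PM variance fell below zero under the "
                "cov(theta_M, theta_T) ~ var(theta_M) approximation; floored at 0",
                stacklevel=2,
            )
            rel = 0.0
        var_pm = pm**2 * rel
    return Effect(pm, float(np.sqrt(var_pm)))


def decompose(
    model1: FEFit,
    model2: FEFit,
    model3: FEFit,
    exposure: str = "exposure",
    mediator: str = "mediator",
    **labels,
) -> MediationEstimate:
    """Combine the three fits into the mediation decomposition.

    ``model1``: outcome ~ exposure; ``model2``: outcome ~ exposure +
    mediator; ``model3``: mediator ~ exposure.  All three must come from the
    same stratum panel.
    """
    if mediator not in model2.params.index:
        raise ValueError(f"model2 does not include the mediator {mediator!r}")
    theta_t = float(model1.params[exposure])
    theta_a = float(model2.params[exposure])
    alpha = float(model3.params[exposure])
    beta = float(model2.params[mediator])
    theta_m = alpha * beta
    var_m = beta**2 * model3.var(exposure) + alpha**2 * model2.var(mediator)
    total = Effect(theta_t, np.sqrt(model1.var(exposure)))
    alternative = Effect(theta_a, np.sqrt(model2.var(exposure)))
    mediation_ = Effect(theta_m, np.sqrt(var_m))
    pm = proportion_mediated(theta_m, theta_t, var_m, model1.var(exposure))
    return MediationEstimate(
        total=total,
        mediation=mediation_,
        alternative=alternative,
        pm=pm,
        n_obs=model1.n_obs,
        n_countries=0,
        **labels,
    )


def mediate_stratum(panel, cluster_by_country: bool = False, **labels) -> MediationEstimate:
    """Run the three fixed-effects models and the decomposition on one
    stratum panel."""
    m1 = fit_twoway_fe(panel, "outcome", ["exposure"], cluster_by_country)
    m2 = fit_twoway_fe(panel, "outcome", ["exposure", "mediator"], cluster_by_country)
    m3 = fit_twoway_fe(panel, "mediator", ["exposure"], cluster_by_country)
    est = decompose(m1, m2, m3, **labels)
    df = getattr(panel, "data", panel)
    est.n_countries = df["country"].nunique()
    return est


def run_mediation(
    panel,
    stratify: bool = True,
    cluster_by_country: bool = False,
) -> list[MediationEstimate]:
    """Mediation estimates for every income-group x pandemic-year stratum of
    the panel (or a single unstratified estimate with ``stratify=False``)."""
    term = getattr(panel, "term", None)
    if not stratify:
        return [mediate_stratum(panel, cluster_by_country, term=term)]
    out = []
    for inc, yr, sub in panel.strata():
        out.append(
            mediate_stratum(sub, cluster_by_country, term=term, income_group=inc, pandemic_year=yr)
        )
    if not out:
        raise ValueError("panel has no rows within the pandemic-year windows")
    return out


def bootstrap_se(panel, n_boot: int = 500, seed: int = 0) -> dict[str, float]:
    """Country-level nonparametric bootstrap standard errors.

    Countries are resampled with replacement; duplicated draws are relabeled
    so each acts as its own fixed-effect unit (the standard cluster
    bootstrap).  Returns SDs of the four quantities across resamples.
    """
    df = getattr(panel, "data", panel).copy()
    rng = np.random.default_rng(seed)
    countries = df["country"].unique()
    groups = {c: df[df["country"] == c] for c in countries}
    stats_: dict[str, list[float]] = {k: [] for k in ("total", "mediation", "alternative", "pm")}
    for _ in range(n_boot):
        draw = rng.choice(countries, size=len(countries), replace=True)
        frames = []
        for i, c in enumerate(draw):
            g = groups[c].copy()
            g["country"] = f"bs{i}"
            frames.append(g)
        sample = pd.concat(frames, ignore_index=True)
        try:
            with warnings.catch_warnings():
                # the PM variance floor is irrelevant inside resamples: only
                # point estimates are collected here
                warnings.simplefilter("ignore", UserWarning)
                est = mediate_stratum(sample)
        except (ValueError, ZeroDivisionError):
            continue
        stats_["total"].append(est.total.estimate)
        stats_["mediation"].append(est.mediation.estimate)
        stats_["alternative"].append(est.alternative.estimate)
        stats_["pm"].append(est.pm.estimate)
    return {k: float(np.std(v, ddof=1)) for k, v in stats_.items()}
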