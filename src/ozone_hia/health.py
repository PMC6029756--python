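"""Attributable-mortality estimation from city exposure and CRFs.

The concentration–response function (CRF) for a stratum is reported as the
percent increase in daily mortality per 10 μg/m³ (≈ 5 ppb) of MDA8 ozone.
On the log (GLM link) scale the per-ppb coefficient is

    β = ln(1 + pct/100) / 5

and for a day with city-level concentration C (ppb) the attributable
fraction and attributable daily deaths are

    AF  = 1 − exp(−β·C)                 (0 ≤ AF < 1, no threshold)
    ADD = Y_b · POP · AF = baseline · AF

Annual attributable deaths are the sum of ADD over covered days rescaled to
a 365.25-day year, so periods with identical coverage are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import UGM3_PER_PPB, season_mask
from .synthetic import AGE_GROUPS, PopulationScenario

__all__ = [
    "CRFEntry",
    "default_crf_table",
    "beta_from_percent",
    "attributable_fraction",
    "attributable_daily_deaths",
    "annualize",
    "annual_attributable",
    "scale_future_baseline",
    "excess_mortality",
    "run_stratified_assessment",
]

#: ppb increment equivalent to the CRF's 10-μg/m³ reporting increment
PPB_PER_CRF_INCREMENT = 10.0 / UGM3_PER_PPB  # = 5 ppb

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CRFEntry:
    """Percent increase (95% CI) in daily mortality per 10 μg/m³ MDA8 ozone."""

    stratum_type: str
    stratum: str
    pct: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.pct <= self.ci_high):
            raise ValueError("CI must bracket the central estimate")

    @property
    def beta(self) -> float:
        return beta_from_percent(self.pct)


# Pooled two-stage (GLM + hierarchical Bayes) estimates from the 272-city
# Chinese time-series analysis the assessment is built on.
_DEFAULT_CRFS = [
    ("cause", "non-accidental", 0.24, 0.13, 0.35),
    ("cause", "cardiovascular", 0.27, 0.10, 0.44),
    ("cause", "respiratory", 0.18, -0.11, 0.47),
    ("age", "5-64", 0.13, -0.23, 0.48),
    ("age", "65-74", 0.19, 0.03, 0.34),
    ("age", "75+", 0.42, 0.21, 0.64),
    ("season", "warm", 0.20, 0.08, 0.31),
    ("season", "cold", 0.43, 0.21, 0.65),
]


def default_crf_table() -> pd.DataFrame:
    """CRF table (stratum_type, stratum, pct, ci_low, ci_high) with defaults."""
    return pd.DataFrame(
        _DEFAULT_CRFS, columns=["stratum_type", "stratum", "pct", "ci_low", "ci_high"]
    )


def beta_from_percent(pct):
    """Per-ppb log-scale coefficient from a percent-per-10-μg/m³ CRF."""
    arr = np.asarray(pct, dtype=float)
    if np.any(arr <= -100):
        raise ValueError("percent change must exceed -100")
    out = np.log1p(arr / 100.0) / PPB_PER_CRF_INCREMENT
    return float(out) if arr.ndim == 0 else out


def attributable_fraction(beta, concentration):
    """AF = 1 − exp(−β·C); accepts broadcastable arrays; C must be ≥ 0."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c[~np.isnan(c)] < 0):
        raise ValueError("negative concentration")
    out = -np.expm1(-np.asarray(beta, dtype=float) * c)
    return float(out) if out.ndim == 0 else out


def attributable_daily_deaths(baseline_daily_deaths, af):
    """ADD = baseline daily deaths × AF (baseline = Y_b × POP)."""
    b = np.asarray(baseline_daily_deaths, dtype=float)
    if np.any(b[~np.isnan(b)] < 0):
        raise ValueError("negative baseline deaths")
    out = b * np.asarray(af, dtype=float)
    return float(out) if out.ndim == 0 else out


def annualize(add_series) -> float:
    """Deaths/year from a daily ADD series: sum over covered days ÷ covered years.

    Covered days are those with a defined ADD; missing days are excluded
    from both the sum and the time base, so a series with half its days
    missing and constant ADD elsewhere still annualizes to 365.25 × ADD.
    """
    v = np.asarray(add_series, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no covered days to annualize")
    return float(v.sum() / (v.size / DAYS_PER_YEAR))


def annual_attributable(concentration, baseline_daily_deaths: float, beta,
                        months=None, season: str | None = None,
                        lag_window: int = 1):
    """Annualized attributable deaths for one exposure series.

    ``beta`` may be a scalar or a (D,) vector of coefficient draws (the
    result is then a (D,) vector computed over the same covered days).
    ``season`` restricts the series to warm/cold months (``months`` supplies
    the calendar months when ``concentration`` is a bare array).
    ``lag_window`` > 1 replaces each day's exposure with the trailing moving
    average over that many days (e.g. 4 for a lag-0–3 CRF exposure window);
    annual sums are nearly invariant to this choice for smooth series.
    """
    if isinstance(concentration, pd.Series):
        months = pd.DatetimeIndex(concentration.index).month
        c = concentration.to_numpy(dtype=float)
    else:
        c = np.asarray(concentration, dtype=float)
    if lag_window > 1:
        c = (pd.Series(c).rolling(lag_window, min_periods=1).mean()
             .to_numpy(dtype=float))
    if season is not None:
        if months is None:
            raise ValueError("season selection requires calendar months")
        c = c[season_mask(np.asarray(months), season)]
    c = c[~np.isnan(c)]
    if c.size == 0:
        raise ValueError("no covered days to annualize")
    beta_arr = np.asarray(beta, dtype=float)
    af = -np.expm1(-beta_arr.reshape(beta_arr.shape + (1,)) * c)
    annual = baseline_daily_deaths * af.sum(axis=-1) / (c.size / DAYS_PER_YEAR)
    return float(annual) if beta_arr.ndim == 0 else annual


def scale_future_baseline(baseline: pd.DataFrame, scenario: PopulationScenario,
                          include_aging: bool = True,
                          include_rate_change: bool = True,
                          rate_draw: dict | None = None) -> pd.DataFrame:
    """Future baseline daily deaths under a population scenario.

    Age strata scale by the age-group population ratio
    (pop₂₀₅₀·f₂₀₅₀ₐ)/(pop₂₀₁₀·f₂₀₁₀ₐ) times the mortality-rate ratio (if
    ``include_rate_change``); with ``include_aging`` off they scale by the
    total-size ratio only. Cause and season strata keep constant counts (no
    future projections exist for them). ``rate_draw`` overrides the central
    rate ratios, e.g. with one Monte Carlo draw per age group.
    """
    out = baseline.copy()
    pop_ratio = (scenario.city_pop_2050 / scenario.city_pop_2010)
    age_rows = out["stratum_type"] == "age"
    if not age_rows.any():
        return out
    cities = out.loc[age_rows, "city_id"]
    ratio_by_city = pop_ratio.reindex(cities).to_numpy()
    if include_aging:
        f10 = out.loc[age_rows, "stratum"].map(scenario.age_fraction_2010).to_numpy()
        f50 = out.loc[age_rows, "stratum"].map(scenario.age_fraction_2050).to_numpy()
        if np.any(f10 <= 0):
            raise ValueError("zero historical age-group population share")
        factor = ratio_by_city * f50 / f10
    else:
        factor = ratio_by_city
    if include_rate_change:
        rates = rate_draw if rate_draw is not None else {
            a: scenario.rate_ratio[a][0] for a in AGE_GROUPS}
        factor = factor * out.loc[age_rows, "stratum"].map(rates).to_numpy()
    out.loc[age_rows, "mean_daily_deaths"] = (
        out.loc[age_rows, "mean_daily_deaths"].to_numpy() * factor)
    return out


def excess_mortality(future_annual, historical_annual) -> tuple[float, float]:
    """(absolute delta, percent change); vectors are summed before the percent."""
    f = float(np.asarray(future_annual, dtype=float).sum())
    h = float(np.asarray(historical_annual, dtype=float).sum())
    delta = f - h
    pct = 100.0 * delta / h if h != 0 else float("nan")
    return delta, pct


def run_stratified_assessment(hist_exposure: pd.DataFrame,
                              future_exposures: dict,
                              crfs: pd.DataFrame,
                              baseline: pd.DataFrame,
                              pop_scenarios: list[PopulationScenario],
                              ) -> pd.DataFrame:
    """Point-estimate attributable mortality for every stratum × scenario cell.

    ``hist_exposure`` is a wide city exposure frame (index date, column per
    city); ``future_exposures`` maps (rcp, member) to similar frames. For
    each ensemble member the assessment covers 3 causes (all-age), 3 age
    groups and 2 seasons (season CRFs applied only to their own days),
    crossed with RCP × population scenarios. Cause and season strata use
    constant future baselines; age strata under aging scenarios use the full
    size + aging + rate-change ladder.

    Returns a tidy frame: city, stratum_type, stratum, rcp, pop_scenario,
    member, hist_annual, future_annual, excess, pct_change.
    """
    crf_map = {(r.stratum_type, r.stratum): beta_from_percent(r.pct)
               for r in crfs.itertuples()}
    rcps = sorted({k[0] for k in future_exposures})
    members = sorted({k[1] for k in future_exposures})
    rows = []
    for pop in pop_scenarios:
        nochange = pop.scenario_id == "NOCHANGE"
        fut_base_df = scale_future_baseline(
            baseline, pop, include_aging=not nochange,
            include_rate_change=not nochange)
        fut_base = {(r.city_id, r.stratum_type, r.stratum): r.mean_daily_deaths
                    for r in fut_base_df.itertuples()}
        for rcp in rcps:
            for member in members:
                fut_exp = future_exposures[(rcp, member)]
                for r in baseline.itertuples():
                    beta = crf_map[(r.stratum_type, r.stratum)]
                    season = r.stratum if r.stratum_type == "season" else None
                    hseries = hist_exposure[r.city_id]
                    fseries = fut_exp[r.city_id]
                    hist_annual = annual_attributable(
                        hseries, r.mean_daily_deaths, beta, season=season)
                    fb = fut_base[(r.city_id, r.stratum_type, r.stratum)]
                    fut_annual = annual_attributable(fseries, fb, beta, season=season)
                    delta, pct = excess_mortality(fut_annual, hist_annual)
                    rows.append((r.city_id, r.stratum_type, r.stratum, rcp,
                                 pop.scenario_id, member, hist_annual, fut_annual,
                                 delta, pct))
    return pd.DataFrame(rows, columns=[
        "city_id", "stratum_type", "stratum", "rcp", "pop_scenario", "member",
        "hist_annual", "future_annual", "excess", "pct_change"])
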