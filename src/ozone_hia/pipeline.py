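"""End-to-end experiment: synthetic inputs → BCSD → health impact → uncertainty.

:func:`run_experiment` executes the full design — 2 emission scenarios × 6
population scenarios × ensemble members — on synthetic data and produces:

* a scenario × stratum summary of ensemble-mean excess deaths with
  empirical confidence intervals (the main results table shape),
* a seasonal (warm/cold) summary with the net yearly change,
* a four-driver decomposition per (scenario, SSP-like population scenario),
* stage diagnostics (mean model bias before/after correction, recovered
  seasonal ozone deltas, exceedance fractions).

:func:`resolution_sensitivity` re-runs the cause-specific assessment on
coarse-cell city exposures (no downscaling) and reports the difference
against the fine-scale result.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr

from . import health, metrics, uncertainty
from .downscaling import downscale
from .synthetic import (
    AGE_GROUPS,
    CAUSES,
    TruthConfig,
    generate_baseline_mortality,
    generate_cities,
    generate_city_geometry_weights,
    generate_coarse_model_daily,
    generate_population_scenarios,
    generate_site_hourly_obs,
    generate_sites,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "resolution_sensitivity"]

SCENARIOS = ("rcp45", "rcp85")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one full synthetic experiment."""

    truth: TruthConfig = dc_field(default_factory=TruthConfig)
    n_draws: int = 1000
    quantile_points: int = 99
    exceedance_threshold_ppb: float = 50.0
    scenarios: tuple = SCENARIOS

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario {s!r}")


@dataclass
class ExperimentResult:
    """Everything the experiment computed, plus the inputs it generated."""

    config: ExperimentConfig
    cities: pd.DataFrame
    sites: pd.DataFrame
    weights_fine: pd.DataFrame
    weights_coarse: pd.DataFrame
    baseline: pd.DataFrame
    crfs: pd.DataFrame
    pop_scenarios: list
    hist_exposure: pd.DataFrame
    hist_exposure_coarse: pd.DataFrame
    future_exposures: dict
    future_exposures_coarse: dict
    assessment: pd.DataFrame
    summary: pd.DataFrame
    seasonal: pd.DataFrame
    decomposition: pd.DataFrame
    diagnostics: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------


def _af_annual(series: pd.Series, betas, season=None):
    """Annual attributable deaths per unit baseline (baseline = 1)."""
    return health.annual_attributable(series, 1.0, betas, season=season)


def _build_af_cache(hist_exposure, future_exposures, crfs, crf_draws):
    """Per-(stratum, exposure, city) annualized AF factors, point and per-draw."""
    point, draws = {}, {}
    exposures = {"hist": hist_exposure, **future_exposures}
    for r in crfs.itertuples():
        skey = (r.stratum_type, r.stratum)
        season = r.stratum if r.stratum_type == "season" else None
        beta_pt = health.beta_from_percent(r.pct)
        beta_dr = health.beta_from_percent(crf_draws[skey].to_numpy())
        for ekey, exp_df in exposures.items():
            for city in exp_df.columns:
                s = exp_df[city]
                point[(skey, ekey, city)] = _af_annual(s, beta_pt, season)
                draws[(skey, ekey, city)] = _af_annual(s, beta_dr, season)
    return point, draws


def _baseline_map(baseline: pd.DataFrame) -> dict:
    return {(r.city_id, r.stratum_type, r.stratum): r.mean_daily_deaths
            for r in baseline.itertuples()}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    cfg = config.truth
    cities = generate_cities(cfg)
    sites = generate_sites(cfg, cities)
    weights_fine = generate_city_geometry_weights(cfg, cities, grid="fine")
    weights_coarse = generate_city_geometry_weights(cfg, cities, grid="coarse")
    baseline = generate_baseline_mortality(cfg)
    pop_scenarios = generate_population_scenarios(cfg)
    crfs = health.default_crf_table()

    # --- observations -> gridded products
    hourly = generate_site_hourly_obs(cfg, sites)
    site_daily = metrics.site_daily_mda8(hourly)
    obs_fine = metrics.grid_site_daily(site_daily, cfg.fine_grid,
                                       times=cfg.dates("historical"))
    obs_coarse = metrics.aggregate_fine_to_coarse(obs_fine, cfg.coarse_grid)
    clim_fine = metrics.monthly_climatology(obs_fine)
    clim_coarse = metrics.monthly_climatology(obs_coarse)

    hist_exposure = metrics.city_series_from_grid(obs_fine, weights_fine)
    hist_exposure_coarse = metrics.city_series_from_grid(obs_coarse, weights_coarse)

    # --- downscale each scenario / member and build city exposures
    future_exposures = {}
    future_exposures_coarse = {}
    bias_before, bias_after = [], []
    for rcp in config.scenarios:
        for member in range(1, cfg.n_ensemble + 1):
            model = generate_coarse_model_daily(cfg, rcp, member)
            ds = downscale(model["historical"], model["future"], obs_coarse,
                           clim_coarse, clim_fine, K=config.quantile_points)
            future_exposures[(rcp, member)] = metrics.city_series_from_grid(
                ds.future_fine, weights_fine)
            future_exposures_coarse[(rcp, member)] = metrics.city_series_from_grid(
                ds.future_corrected_coarse, weights_coarse)
            bias_before.append(ds.diagnostics["mean_bias_before_ppb"])
            bias_after.append(ds.diagnostics["mean_bias_after_ppb"])

    # --- point assessment over the full stratification
    assessment = health.run_stratified_assessment(
        hist_exposure, future_exposures, crfs, baseline, pop_scenarios)

    # --- Monte Carlo machinery
    draw_spec = uncertainty.DrawSpec(n_draws=config.n_draws, seed=cfg.seed)
    crf_draws = uncertainty.sample_crf_draws(draw_spec, crfs)
    rate_draws = uncertainty.sample_rate_ratio_draws(
        draw_spec, next(p for p in pop_scenarios if p.scenario_id != "NOCHANGE")
        .rate_ratio) if len(pop_scenarios) > 1 else None
    af_point, af_draws = _build_af_cache(hist_exposure, future_exposures,
                                         crfs, crf_draws)
    bmap = _baseline_map(baseline)
    city_ids = list(hist_exposure.columns)
    members = sorted({k[1] for k in future_exposures})

    summary = _summarize(config, city_ids, members, pop_scenarios, af_point,
                         af_draws, bmap, rate_draws)
    seasonal = _seasonal_summary(config, city_ids, members, af_point, af_draws, bmap)
    decomposition = _decompose(config, city_ids, members, pop_scenarios,
                               af_point, bmap)

    diagnostics = _diagnostics(config, hist_exposure, future_exposures,
                               bias_before, bias_after)
    return ExperimentResult(
        config=config, cities=cities, sites=sites, weights_fine=weights_fine,
        weights_coarse=weights_coarse, baseline=baseline, crfs=crfs,
        pop_scenarios=pop_scenarios, hist_exposure=hist_exposure,
        hist_exposure_coarse=hist_exposure_coarse,
        future_exposures=future_exposures,
        future_exposures_coarse=future_exposures_coarse,
        assessment=assessment, summary=summary, seasonal=seasonal,
        decomposition=decomposition, diagnostics=diagnostics)


def _age_future_baseline(pop, bmap, city_ids, include_size, include_aging,
                         include_rates, rate_row=None):
    """Future age-stratum baselines b'_{c,a}; rate_row optionally per-draw ratios."""
    out = {}
    for c in city_ids:
        size_ratio = (pop.city_pop_2050[c] / pop.city_pop_2010[c]) if include_size else 1.0
        for a in AGE_GROUPS:
            f = size_ratio
            if include_aging:
                f *= pop.age_fraction_2050[a] / pop.age_fraction_2010[a]
            if include_rates:
                f *= rate_row[a] if rate_row is not None else pop.rate_ratio[a][0]
            out[(c, a)] = bmap[(c, "age", a)] * f
    return out


def _summarize(config, city_ids, members, pop_scenarios, af_point, af_draws,
               bmap, rate_draws):
    """Main-results table: ensemble-mean excess with pooled-draw eCIs."""
    rows = []

    def add_row(pop_id, stype, stratum, hist, fut_mean, excess_by_member_point,
                excess_draws, rcp):
        exc = float(np.mean(excess_by_member_point))
        lo, hi = uncertainty.empirical_ci(excess_draws)
        rows.append((rcp, pop_id, stype, stratum, hist, fut_mean, exc,
                     100.0 * exc / hist if hist else np.nan, lo, hi))

    rcps = sorted({e[0] for (_, e, _) in af_point if isinstance(e, tuple)})

    for rcp in rcps:
        # cause strata under no population change (constant baselines)
        for cause in CAUSES:
            skey = ("cause", cause)
            hist = sum(bmap[(c, *skey)] * af_point[(skey, "hist", c)]
                       for c in city_ids)
            exc_pt = [sum(bmap[(c, *skey)]
                          * (af_point[(skey, (rcp, m), c)] - af_point[(skey, "hist", c)])
                          for c in city_ids) for m in members]
            exc_dr = np.stack([
                sum(bmap[(c, *skey)]
                    * (af_draws[(skey, (rcp, m), c)] - af_draws[(skey, "hist", c)])
                    for c in city_ids) for m in members])
            fut_mean = hist + float(np.mean(exc_pt))
            add_row("NOCHANGE", "cause", cause, hist, fut_mean, exc_pt, exc_dr, rcp)

        # age-summed burden under each population scenario (full ladder for
        # the aging scenarios, identity for NOCHANGE)
        for pop in pop_scenarios:
            nochange = pop.scenario_id == "NOCHANGE"
            hist = sum(bmap[(c, "age", a)] * af_point[(("age", a), "hist", c)]
                       for c in city_ids for a in AGE_GROUPS)
            fb = _age_future_baseline(pop, bmap, city_ids,
                                      include_size=not nochange,
                                      include_aging=not nochange,
                                      include_rates=not nochange)
            exc_pt = [sum(fb[(c, a)] * af_point[(("age", a), (rcp, m), c)]
                          - bmap[(c, "age", a)] * af_point[(("age", a), "hist", c)]
                          for c in city_ids for a in AGE_GROUPS)
                      for m in members]
            exc_dr = []
            for m in members:
                total = 0.0
                for a in AGE_GROUPS:
                    skey = ("age", a)
                    rate_mult = (np.ones(config.n_draws) if nochange or rate_draws is None
                                 else rate_draws[a].to_numpy())
                    for c in city_ids:
                        fb_static = _static_age_factor(pop, c, a, nochange)
                        fut_b = bmap[(c, "age", a)] * fb_static * rate_mult
                        total = total + (fut_b * af_draws[(skey, (rcp, m), c)]
                                         - bmap[(c, "age", a)] * af_draws[(skey, "hist", c)])
                exc_dr.append(total)
            fut_mean = hist + float(np.mean(exc_pt))
            add_row(pop.scenario_id, "age", "age-summed", hist, fut_mean,
                    exc_pt, np.stack(exc_dr), rcp)

    return pd.DataFrame(rows, columns=[
        "rcp", "pop_scenario", "stratum_type", "stratum", "hist_annual",
        "future_annual_mean", "excess_mean", "pct_change", "eci_low", "eci_high"])


def _static_age_factor(pop, city, age, nochange):
    """Size × aging scaling factor, excluding the (possibly drawn) rate ratio."""
    if nochange:
        return 1.0
    return (pop.city_pop_2050[city] / pop.city_pop_2010[city]
            * pop.age_fraction_2050[age] / pop.age_fraction_2010[age])


def _seasonal_summary(config, city_ids, members, af_point, af_draws, bmap):
    """Warm/cold burden changes and the draw-consistent net yearly change."""
    rows = []
    rcps = sorted({e[0] for (_, e, _) in af_point if isinstance(e, tuple)})
    for rcp in rcps:
        season_stats = {}
        for season in ("warm", "cold"):
            skey = ("season", season)
            hist = sum(bmap[(c, *skey)] * af_point[(skey, "hist", c)]
                       for c in city_ids)
            exc_pt = [sum(bmap[(c, *skey)]
                          * (af_point[(skey, (rcp, m), c)] - af_point[(skey, "hist", c)])
                          for c in city_ids) for m in members]
            hist_dr = sum(bmap[(c, *skey)] * af_draws[(skey, "hist", c)]
                          for c in city_ids)
            fut_dr = np.stack([sum(bmap[(c, *skey)] * af_draws[(skey, (rcp, m), c)]
                                   for c in city_ids) for m in members])
            exc = float(np.mean(exc_pt))
            lo, hi = uncertainty.empirical_ci(fut_dr - hist_dr)
            rows.append((rcp, season, hist, exc,
                         100.0 * exc / hist if hist else np.nan, lo, hi))
            season_stats[season] = (hist, exc, hist_dr, fut_dr)

        hist_tot = sum(v[0] for v in season_stats.values())
        exc_tot = sum(v[1] for v in season_stats.values())
        hist_dr_tot = sum(v[2] for v in season_stats.values())
        fut_dr_tot = sum(v[3] for v in season_stats.values())
        with np.errstate(divide="ignore", invalid="ignore"):
            net_pct_draws = 100.0 * (fut_dr_tot - hist_dr_tot) / hist_dr_tot
        lo, hi = uncertainty.empirical_ci(net_pct_draws)
        rows.append((rcp, "net", hist_tot, exc_tot,
                     100.0 * exc_tot / hist_tot if hist_tot else np.nan, lo, hi))
    df = pd.DataFrame(rows, columns=["rcp", "season", "hist_annual", "excess_mean",
                                     "pct_change", "eci_low", "eci_high"])
    # the net row's eCI is on the percent scale; seasonal rows on deaths/year
    df["eci_scale"] = np.where(df["season"] == "net", "percent", "deaths")
    return df


def _decompose(config, city_ids, members, pop_scenarios, af_point, bmap):
    """Four-driver decomposition per (rcp, aging scenario), at point estimates."""
    rcps = sorted({e[0] for (_, e, _) in af_point if isinstance(e, tuple)})
    rows = []
    hist = sum(bmap[(c, "age", a)] * af_point[(("age", a), "hist", c)]
               for c in city_ids for a in AGE_GROUPS)
    for rcp in rcps:
        for pop in pop_scenarios:
            if pop.scenario_id == "NOCHANGE":
                continue

            def run_excess(include_size, include_aging, include_rates, _pop=pop,
                           _rcp=rcp):
                fb = _age_future_baseline(_pop, bmap, city_ids, include_size,
                                          include_aging, include_rates)
                per_member = [
                    sum(fb[(c, a)] * af_point[(("age", a), (_rcp, m), c)]
                        - bmap[(c, "age", a)] * af_point[(("age", a), "hist", c)]
                        for c in city_ids for a in AGE_GROUPS)
                    for m in members]
                return float(np.mean(per_member))

            contrib = uncertainty.decompose_drivers(run_excess, rcp,
                                                    pop.scenario_id, hist)
            rows.append((rcp, pop.scenario_id, contrib.climate, contrib.size,
                         contrib.aging, contrib.rate, contrib.total, hist,
                         contrib.percent.get("total", np.nan)))
    return pd.DataFrame(rows, columns=[
        "rcp", "pop_scenario", "climate_effect", "size_effect", "aging_effect",
        "rate_effect", "total", "hist_annual", "total_pct"])


def _diagnostics(config, hist_exposure, future_exposures, bias_before, bias_after):
    th = config.exceedance_threshold_ppb
    city_hist_means = hist_exposure.mean()
    diags = {
        "hist_mean_ozone_ppb": float(city_hist_means.mean()),
        "hist_exceedance_fraction": float(np.mean(
            [metrics.exceedance_fraction(hist_exposure[c], th)
             for c in hist_exposure.columns])),
        "mean_bias_before_ppb": float(np.mean(bias_before)),
        "mean_bias_after_ppb": float(np.mean(bias_after)),
    }
    rcps = sorted({k[0] for k in future_exposures})
    members = sorted({k[1] for k in future_exposures})
    for rcp in rcps:
        fut_mean = np.mean([future_exposures[(rcp, m)].mean().mean()
                            for m in members])
        diags[f"{rcp}_future_mean_ozone_ppb"] = float(fut_mean)
        diags[f"{rcp}_future_exceedance_fraction"] = float(np.mean(
            [metrics.exceedance_fraction(future_exposures[(rcp, m)][c], th)
             for m in members for c in hist_exposure.columns]))
        for season in ("warm", "cold"):
            h = np.mean([metrics.period_mean(hist_exposure[c], season)
                         for c in hist_exposure.columns])
            f = np.mean([metrics.period_mean(future_exposures[(rcp, m)][c], season)
                         for m in members for c in hist_exposure.columns])
            diags[f"{rcp}_{season}_delta_ppb"] = float(f - h)
    return diags


# ---------------------------------------------------------------------------


def resolution_sensitivity(result: ExperimentResult) -> pd.DataFrame:
    """Coarse- vs fine-resolution cause-specific excess under no population change.

    For each city and cause, the assessment is repeated with city exposures
    built directly from the bias-corrected coarse fields (historical side:
    coarse-gridded observations). Reports absolute and percent differences
    of the ensemble-mean excess, plus the ozone-change difference, and
    aggregate rows (city_id = 'ALL').
    """
    crfs = result.crfs
    bmap = _baseline_map(result.baseline)
    members = sorted({k[1] for k in result.future_exposures})
    rcps = sorted({k[0] for k in result.future_exposures})
    rows = []
    for rcp in rcps:
        for cause in CAUSES:
            beta = health.beta_from_percent(
                crfs.set_index(["stratum_type", "stratum"]).loc[("cause", cause), "pct"])
            per_city = {}
            for c in result.hist_exposure.columns:
                b = bmap[(c, "cause", cause)]
                hist_f = health.annual_attributable(result.hist_exposure[c], b, beta)
                hist_c = health.annual_attributable(result.hist_exposure_coarse[c], b, beta)
                exc_f = np.mean([health.annual_attributable(
                    result.future_exposures[(rcp, m)][c], b, beta) - hist_f
                    for m in members])
                exc_c = np.mean([health.annual_attributable(
                    result.future_exposures_coarse[(rcp, m)][c], b, beta) - hist_c
                    for m in members])
                d_ozone_f = np.mean([result.future_exposures[(rcp, m)][c].mean()
                                     for m in members]) - result.hist_exposure[c].mean()
                d_ozone_c = np.mean([result.future_exposures_coarse[(rcp, m)][c].mean()
                                     for m in members]) - result.hist_exposure_coarse[c].mean()
                per_city[c] = (exc_f, exc_c, d_ozone_f, d_ozone_c)
                rows.append((rcp, cause, c, exc_f, exc_c, exc_c - exc_f,
                             100.0 * (exc_c - exc_f) / abs(exc_f) if exc_f else np.nan,
                             d_ozone_c - d_ozone_f))
            tf = sum(v[0] for v in per_city.values())
            tc = sum(v[1] for v in per_city.values())
            dzf = np.mean([v[2] for v in per_city.values()])
            dzc = np.mean([v[3] for v in per_city.values()])
            rows.append((rcp, cause, "ALL", tf, tc, tc - tf,
                         100.0 * (tc - tf) / abs(tf) if tf else np.nan, dzc - dzf))
    return pd.DataFrame(rows, columns=[
        "rcp", "cause", "city_id", "excess_fine", "excess_coarse",
        "abs_difference", "pct_difference", "ozone_change_diff_ppb"])
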