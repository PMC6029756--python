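"""Monte Carlo uncertainty and driver decomposition.

Empirical confidence intervals (eCIs) pool the outcome distribution across
coefficient draws and ensemble members (default 1,000 draws × 3 members =
3,000 values) and take the 2.5th/97.5th percentiles with the
linear-interpolation percentile rule. CRF draws are normal on the reported
percent scale with sd = (ci_high − ci_low) / (2 × 1.959964); mortality-rate
-ratio draws are normal on the ratio scale, truncated at 0.

The change in burden between periods is decomposed into four drivers by
running the assessment incrementally — no population change; + size;
+ aging; + rate change — so the four contributions telescope exactly to the
total change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import AGE_GROUPS

__all__ = [
    "DrawSpec",
    "normal_sd_from_ci",
    "sample_crf_draws",
    "sample_rate_ratio_draws",
    "empirical_ci",
    "ensemble_mean",
    "DriverContribution",
    "decompose_drivers",
]

_Z975 = 1.959964


def normal_sd_from_ci(ci_low, ci_high) -> float:
    """Normal sd implied by a symmetric 95% interval."""
    return (np.asarray(ci_high, dtype=float) - np.asarray(ci_low, dtype=float)) / (2 * _Z975)


@dataclass(frozen=True)
class DrawSpec:
    """Monte Carlo configuration: number of coefficient draws and seed."""

    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 90, stream]))


def sample_crf_draws(spec: DrawSpec, crfs: pd.DataFrame) -> pd.DataFrame:
    """(n_draws × stratum) table of CRF percent draws, reproducible given seed.

    One draw per stratum per iteration, shared downstream across cities and
    ensemble members so totals within a draw are coherent.
    """
    rng = spec.rng(0)
    cols = {}
    for r in crfs.itertuples():
        sd = normal_sd_from_ci(r.ci_low, r.ci_high)
        cols[(r.stratum_type, r.stratum)] = rng.normal(r.pct, sd, size=spec.n_draws)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["stratum_type", "stratum"])
    out.index.name = "draw"
    return out


def sample_rate_ratio_draws(spec: DrawSpec, rate_ratios: dict) -> pd.DataFrame:
    """(n_draws × age group) mortality-rate-ratio draws, truncated at 0.

    ``rate_ratios`` maps age group -> (central, pi_low, pi_high). Negative
    rates are unphysical; truncation events are counted and warned about.
    """
    rng = spec.rng(1)
    cols = {}
    n_truncated = 0
    for a in AGE_GROUPS:
        c, lo, hi = rate_ratios[a]
        sd = normal_sd_from_ci(lo, hi)
        draws = rng.normal(c, sd, size=spec.n_draws)
        n_truncated += int((draws < 0).sum())
        cols[a] = np.maximum(draws, 0.0)
    if n_truncated:
        warnings.warn(f"truncated {n_truncated} negative rate-ratio draws at 0",
                      stacklevel=2)
    out = pd.DataFrame(cols)
    out.index.name = "draw"
    return out


def empirical_ci(values, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of a pooled Monte Carlo outcome distribution.

    Linear interpolation between order statistics (the default percentile
    rule); for level 0.95 this is the 2.5th and 97.5th percentiles of the
    pooled draws × members values.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 values for an empirical interval")
    alpha = (1 - level) / 2
    lo, hi = np.percentile(v, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)


def ensemble_mean(values_per_member) -> float:
    """Unweighted mean of the per-member point estimates."""
    v = np.asarray(list(values_per_member), dtype=float)
    if v.size == 0:
        raise ValueError("no ensemble members")
    return float(v.mean())


@dataclass(frozen=True)
class DriverContribution:
    """Incremental contributions (deaths/year) to the change in burden.

    ``climate + size + aging + rate == total`` exactly by construction.
    Percent values are relative to the historical age-stratified annual
    attributable deaths.
    """

    rcp: str
    pop_scenario: str
    climate: float
    size: float
    aging: float
    rate: float
    total: float
    historical: float
    percent: dict = field(default_factory=dict)


def decompose_drivers(run_excess, rcp: str, pop_scenario: str,
                      historical_annual: float) -> DriverContribution:
    """Four-factor incremental decomposition of the burden change.

    ``run_excess(include_size, include_aging, include_rates)`` must return
    the total excess (future − historical, deaths/year) of the age-stratified
    assessment under the given configuration with everything else held fixed:

    * (False, False, False): no population change — the climate/emission effect
    * (True, False, False):  + population size
    * (True, True, False):   + population aging
    * (True, True, True):    + age-group mortality-rate change
    """
    e0 = run_excess(False, False, False)
    e1 = run_excess(True, False, False)
    e2 = run_excess(True, True, False)
    e3 = run_excess(True, True, True)
    climate, size, aging, rate = e0, e1 - e0, e2 - e1, e3 - e2
    pct = {}
    if historical_annual:
        pct = {k: 100.0 * v / historical_annual for k, v in
               [("climate", climate), ("size", size), ("aging", aging),
                ("rate", rate), ("total", e3)]}
    return DriverContribution(rcp=rcp, pop_scenario=pop_scenario, climate=climate,
                              size=size, aging=aging, rate=rate, total=e3,
                              historical=historical_annual, percent=pct)
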