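"""Synthetic study inputs with known ground truth.

Everything downstream of raw data retrieval is exercised against inputs
generated here: hourly monitor observations, coarse-resolution daily MDA8
fields from an emulated global chemistry–climate model (with an injected,
recoverable bias and per-scenario seasonal future trends), city boundary
weights, population scenarios, and baseline mortality tables.

The latent "true" ozone field is a smooth separable function of latitude,
longitude and day-of-year plus an AR(1) daily regional weather term, which
gives the monthly distributions enough quantile structure for the
bias-correction step to be non-trivial. The latent truth is exposed
(:func:`truth_field`, :func:`truth_city_series`) so downscaling error can be
measured against ground truth.

Magnitudes mirror the study conditions the pipeline is designed for:
918-day historical (2013-04-27..2015-10-31) and future (2053-04-27..
2055-10-31) periods, a +17 ppb mean model bias, 10.6% of site-days missing,
3 ensemble members, and per-scenario warm/cold future ozone deltas
(moderate: −16.6 / −1.7 ppb; high: −4.2 / +15.1 ppb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, make_field
from .metrics import count_days_in_period, season_mask

__all__ = [
    "TruthConfig",
    "PopulationScenario",
    "BiasProfile",
    "SCENARIO_ALIASES",
    "DEFAULT_TREND_PROFILE",
    "DEFAULT_RATE_RATIOS",
    "AGE_GROUPS",
    "CAUSES",
    "truth_field",
    "truth_city_series",
    "generate_cities",
    "generate_sites",
    "generate_site_hourly_obs",
    "generate_coarse_model_daily",
    "generate_city_geometry_weights",
    "generate_population_scenarios",
    "generate_baseline_mortality",
]

#: canonical scenario ids and accepted aliases
SCENARIO_ALIASES = {"rcp45": "rcp45", "moderate": "rcp45",
                    "rcp85": "rcp85", "high": "rcp85"}

#: per-scenario seasonal ozone change (ppb) injected into the future period
DEFAULT_TREND_PROFILE = {
    "rcp45": {"warm": -16.6, "cold": -1.7},
    "rcp85": {"warm": -4.2, "cold": 15.1},
}

AGE_GROUPS = ("5-64", "65-74", "75+")
CAUSES = ("non-accidental", "cardiovascular", "respiratory")

#: 2050-vs-2010 age-group mortality-rate change ratios with 95% PIs
DEFAULT_RATE_RATIOS = {
    "5-64": (0.68, 0.35, 1.02),
    "65-74": (0.50, 0.26, 0.73),
    "75+": (0.83, 0.61, 1.05),
}

# RNG stream ids (SeedSequence spawn keys) — fixed so every artifact is
# reproducible independently of generation order.
_STREAM_CITIES = 1
_STREAM_SITES = 2
_STREAM_WEATHER_HIST = 3
_STREAM_WEATHER_FUT = 4
_STREAM_OBS = 5
_STREAM_MEMBER = 6
_STREAM_POP = 7
_STREAM_MORT = 8


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class BiasProfile:
    """Additive model bias. ``constant``: fixed ``mean`` ppb everywhere.

    ``value_linear`` additionally tilts the bias with the field's departure
    from a 40-ppb reference (``slope`` ppb of extra bias per 10 ppb), giving
    a quantile-dependent bias for stress-testing the quantile mapping.
    """

    kind: str = "constant"
    mean: float = 17.0
    slope: float = 0.0

    def __call__(self, values: np.ndarray) -> np.ndarray:
        if self.kind == "constant":
            return np.full_like(values, self.mean)
        if self.kind == "value_linear":
            return self.mean + self.slope * (values - 40.0) / 10.0
        raise ValueError(f"unknown bias profile kind {self.kind!r}")


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth configuration for the synthetic study domain."""

    seed: int = 0
    n_sites: int = 40
    n_cities: int = 10
    coarse_grid: GridSpec = field(
        default_factory=lambda: GridSpec(28.0, 108.0, 2.0, 2.5, 3, 3))
    fine_grid: GridSpec = field(
        default_factory=lambda: GridSpec(28.0, 108.0, 0.25, 0.25, 24, 30))
    historical_period: tuple[str, str] = ("2013-04-27", "2015-10-31")
    future_period: tuple[str, str] = ("2053-04-27", "2055-10-31")
    bias_profile: BiasProfile = field(default_factory=BiasProfile)
    trend_profile: dict = field(default_factory=lambda: DEFAULT_TREND_PROFILE)
    missing_rate: float = 0.106
    hourly_missing_rate: float = 0.01
    n_ensemble: int = 3
    # latent-field shape parameters (ppb)
    base_level: float = 40.0
    seasonal_amplitude: float = 12.0
    spatial_amplitude: float = 5.0
    weather_sd: float = 5.0
    weather_ar1: float = 0.6
    member_sd: float = 2.5
    member_ar1: float = 0.5
    cell_noise_sd: float = 1.5
    site_offset_sd: float = 1.0
    site_day_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        self.coarse_grid.nesting_ratio(self.fine_grid)
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.hourly_missing_rate < 1.0):
            raise ValueError("hourly_missing_rate must be in [0, 1)")
        if self.n_days("historical") != self.n_days("future"):
            raise ValueError("historical and future periods must have equal day counts")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")

    def dates(self, period: str) -> pd.DatetimeIndex:
        start, end = {"historical": self.historical_period,
                      "future": self.future_period}[period]
        return pd.date_range(start, end, freq="D")

    def n_days(self, period: str) -> int:
        start, end = {"historical": self.historical_period,
                      "future": self.future_period}[period]
        return count_days_in_period(start, end)


@dataclass(frozen=True)
class PopulationScenario:
    """One population-change scenario (national age structure, city sizes)."""

    scenario_id: str
    city_pop_2010: pd.Series
    city_pop_2050: pd.Series
    age_fraction_2010: dict
    age_fraction_2050: dict
    rate_ratio: dict  # age group -> (central, pi_low, pi_high)

    def __post_init__(self) -> None:
        for fr in (self.age_fraction_2010, self.age_fraction_2050):
            vals = np.array([fr[a] for a in AGE_GROUPS])
            if np.any(vals < 0) or vals.sum() > 1 + 1e-9:
                raise ValueError("age fractions must be in [0,1] and sum <= 1")
        if (self.city_pop_2010 <= 0).any() or (self.city_pop_2050 <= 0).any():
            raise ValueError("populations must be positive")
        for a, (c, lo, hi) in self.rate_ratio.items():
            if not (lo <= c <= hi):
                raise ValueError(f"rate-ratio PI does not bracket central value for {a}")


# ---------------------------------------------------------------------------
# latent truth


def _weather(cfg: TruthConfig, period: str) -> np.ndarray:
    """Spatially uniform AR(1) daily weather anomaly for one period (ppb)."""
    stream = _STREAM_WEATHER_HIST if period == "historical" else _STREAM_WEATHER_FUT
    rng = _rng(cfg.seed, stream)
    n = cfg.n_days(period)
    phi, sd = cfg.weather_ar1, cfg.weather_sd
    innov_sd = sd * math.sqrt(1 - phi**2)
    w = np.empty(n)
    w[0] = rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n - 1)
    for t in range(1, n):
        w[t] = phi * w[t - 1] + eps[t - 1]
    return w


def _truth_deterministic(cfg: TruthConfig, dates: pd.DatetimeIndex,
                         lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Smooth separable (lat, lon, day-of-year) component, shape (T, *lats.shape)."""
    doy = dates.dayofyear.to_numpy()
    seasonal = cfg.seasonal_amplitude * np.cos(2 * np.pi * (doy - 197) / 365.25)
    g = cfg.coarse_grid
    lat_span = g.lat_max - g.lat0
    lon_span = g.lon_max - g.lon0
    spatial = cfg.spatial_amplitude * (
        np.cos(np.pi * (lats - g.lat0) / lat_span)
        + 0.8 * np.sin(np.pi * (lons - g.lon0) / lon_span)
    )
    return cfg.base_level + seasonal.reshape((-1,) + (1,) * spatial.ndim) + spatial


def _trend(cfg: TruthConfig, scenario: str, months: np.ndarray) -> np.ndarray:
    prof = cfg.trend_profile[SCENARIO_ALIASES[scenario]]
    out = np.where(season_mask(months, "warm"), prof["warm"], prof["cold"])
    return out.astype(float)


def truth_values_at(cfg: TruthConfig, period: str, lats, lons,
                    scenario: str | None = None) -> np.ndarray:
    """Latent true MDA8 at arbitrary points, shape (T, *points*).

    For the future period a ``scenario`` applies its seasonal trend; the
    historical truth is scenario-independent. Clamped at 0 ppb.
    """
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    dates = cfg.dates(period)
    v = _truth_deterministic(cfg, dates, lats, lons)
    v = v + _weather(cfg, period).reshape((-1,) + (1,) * lats.ndim)
    if period == "future":
        if scenario is None:
            raise ValueError("future truth requires a scenario")
        v = v + _trend(cfg, scenario, dates.month.to_numpy()).reshape(
            (-1,) + (1,) * lats.ndim)
    return np.maximum(v, 0.0)


def truth_field(cfg: TruthConfig, grid: GridSpec, period: str = "historical",
                scenario: str | None = None) -> xr.DataArray:
    """Latent truth evaluated at the cell centers of ``grid``."""
    lat2, lon2 = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    v = truth_values_at(cfg, period, lat2, lon2, scenario)
    return make_field(v, cfg.dates(period), grid)


def truth_city_series(cfg: TruthConfig, weights: pd.DataFrame, grid: GridSpec,
                      period: str = "historical",
                      scenario: str | None = None) -> pd.DataFrame:
    """Ground-truth city exposure (weighted truth over member cells)."""
    from .metrics import city_series_from_grid

    return city_series_from_grid(truth_field(cfg, grid, period, scenario), weights)


# ---------------------------------------------------------------------------
# geometry: cities and monitoring sites


def generate_cities(cfg: TruthConfig) -> pd.DataFrame:
    """Synthetic city bounding boxes (columns: city_id, lat/lon min/max)."""
    rng = _rng(cfg.seed, _STREAM_CITIES)
    g = cfg.coarse_grid
    rows = []
    for k in range(cfg.n_cities):
        half_lat = rng.uniform(0.25, 0.6)
        half_lon = rng.uniform(0.3, 0.75)
        clat = rng.uniform(g.lat0 + half_lat, g.lat_max - half_lat)
        clon = rng.uniform(g.lon0 + half_lon, g.lon_max - half_lon)
        rows.append(
            {"city_id": f"city{k:03d}", "lat_min": clat - half_lat,
             "lat_max": clat + half_lat, "lon_min": clon - half_lon,
             "lon_max": clon + half_lon}
        )
    return pd.DataFrame(rows)


def generate_sites(cfg: TruthConfig, cities: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monitor locations: >= 1 site inside every city and every coarse cell.

    The remaining budget up to ``n_sites`` is placed uniformly over the
    domain. Returns columns ``site_id, lat, lon`` plus a ``cities_without_sites``
    attr listing any city left uncovered when ``n_sites`` is too small.
    """
    if cities is None:
        cities = generate_cities(cfg)
    rng = _rng(cfg.seed, _STREAM_SITES)
    g = cfg.coarse_grid
    pts: list[tuple[float, float]] = []
    covered_cities = []
    for _, c in cities.iterrows():
        if len(pts) >= cfg.n_sites:
            break
        pts.append((rng.uniform(c.lat_min, c.lat_max), rng.uniform(c.lon_min, c.lon_max)))
        covered_cities.append(c.city_id)
    # ensure coverage of every coarse cell so each cell has a usable bias map
    for i in range(g.nlat):
        for j in range(g.nlon):
            if len(pts) >= cfg.n_sites:
                break
            ii, jj = g.cell_of([p[0] for p in pts], [p[1] for p in pts])
            if not np.any((ii == i) & (jj == j)):
                pts.append((g.lat0 + (i + rng.uniform(0.2, 0.8)) * g.dlat,
                            g.lon0 + (j + rng.uniform(0.2, 0.8)) * g.dlon))
    while len(pts) < cfg.n_sites:
        pts.append((rng.uniform(g.lat0, g.lat_max), rng.uniform(g.lon0, g.lon_max)))
    df = pd.DataFrame(
        {"site_id": [f"site{k:03d}" for k in range(len(pts))],
         "lat": [p[0] for p in pts], "lon": [p[1] for p in pts]}
    )
    df.attrs["cities_without_sites"] = [
        c for c in cities["city_id"] if c not in covered_cities]
    return df


# ---------------------------------------------------------------------------
# observations and model fields


#: fixed diurnal shape; hourly = daily MDA8 target × profile / (its max 8-h mean),
#: so a complete day's MDA8 recovers the target exactly.
_HOURS = np.arange(24)
_DIURNAL = 0.35 + 0.65 * np.exp(-(((_HOURS - 14.5) / 4.5) ** 2))
_DIURNAL_M8 = max(_DIURNAL[h:h + 8].mean() for h in range(17))


def generate_site_hourly_obs(cfg: TruthConfig, sites: pd.DataFrame | None = None
                             ) -> pd.DataFrame:
    """Hourly monitor observations for the historical period.

    Long table ``site_id, lat, lon, timestamp, o3_ppb``. Site-days are fully
    removed with probability ``missing_rate``; additionally individual hours
    are dropped with probability ``hourly_missing_rate`` so the within-day
    completeness rule is exercised. Deterministic given the config seed.
    """
    if sites is None:
        sites = generate_sites(cfg)
    rng = _rng(cfg.seed, _STREAM_OBS)
    dates = cfg.dates("historical")
    n_sites, n_days = len(sites), len(dates)

    target = truth_values_at(cfg, "historical",
                             sites["lat"].to_numpy(), sites["lon"].to_numpy())  # (T, S)
    offsets = rng.normal(0, cfg.site_offset_sd, size=n_sites)
    target = target + offsets + rng.normal(0, cfg.site_day_noise_sd, size=target.shape)
    target = np.maximum(target, 0.0)

    hourly = target[:, :, None] * (_DIURNAL / _DIURNAL_M8)  # (T, S, 24)
    hourly = hourly * np.maximum(1 + rng.normal(0, 0.03, size=hourly.shape), 0.0)

    drop_day = rng.random((n_days, n_sites)) < cfg.missing_rate
    drop_hour = rng.random(hourly.shape) < cfg.hourly_missing_rate
    keep = ~(drop_day[:, :, None] | drop_hour)

    t_idx, s_idx, h_idx = np.nonzero(keep)
    timestamps = dates[t_idx] + pd.to_timedelta(h_idx, unit="h")
    return pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy()[s_idx],
            "lat": sites["lat"].to_numpy()[s_idx],
            "lon": sites["lon"].to_numpy()[s_idx],
            "timestamp": timestamps,
            "o3_ppb": hourly[t_idx, s_idx, h_idx],
        }
    )


def generate_coarse_model_daily(cfg: TruthConfig, scenario: str, member: int
                                ) -> dict[str, xr.DataArray]:
    """Coarse-grid daily MDA8 from the emulated chemistry–climate model.

    Returns ``{"historical": field, "future": field}``. The historical field
    is the latent truth (shared with observations) plus the configured bias
    and member-specific AR(1)+cell noise; the future field additionally
    carries the scenario's seasonal trend. Deterministic given
    (seed, scenario, member).
    """
    if scenario not in SCENARIO_ALIASES:
        raise ValueError(f"unknown scenario {scenario!r}")
    canon = SCENARIO_ALIASES[scenario]
    if not (1 <= member <= cfg.n_ensemble):
        raise ValueError(f"member must be in 1..{cfg.n_ensemble}")
    g = cfg.coarse_grid
    out = {}
    for p_idx, period in enumerate(("historical", "future")):
        truth = truth_field(cfg, g, period, canon if period == "future" else None)
        v = truth.values
        v = v + cfg.bias_profile(v)
        rng = _rng(cfg.seed, _STREAM_MEMBER,
                   {"rcp45": 0, "rcp85": 1}[canon], member, p_idx)
        n = v.shape[0]
        phi, sd = cfg.member_ar1, cfg.member_sd
        m = np.empty(n)
        m[0] = rng.normal(0, sd)
        eps = rng.normal(0, sd * math.sqrt(1 - phi**2), size=n - 1)
        for t in range(1, n):
            m[t] = phi * m[t - 1] + eps[t - 1]
        v = v + m[:, None, None] + rng.normal(0, cfg.cell_noise_sd, size=v.shape)
        out[period] = make_field(np.maximum(v, 0.0), cfg.dates(period), g)
    return out


# ---------------------------------------------------------------------------
# city weights


def generate_city_geometry_weights(cfg: TruthConfig, cities: pd.DataFrame | None = None,
                                   grid: str | GridSpec = "fine") -> pd.DataFrame:
    """Area-fraction weights of grid cells inside each city boundary.

    ``grid`` is 'fine', 'coarse', or an explicit :class:`GridSpec`. Weights
    are plane lat–lon overlap areas normalized to sum to 1 per city.
    Returns columns ``city_id, lat_idx, lon_idx, weight``.
    """
    if cities is None:
        cities = generate_cities(cfg)
    if isinstance(grid, str):
        grid = {"fine": cfg.fine_grid, "coarse": cfg.coarse_grid}[grid]
    lat_e, lon_e = grid.lat_edges, grid.lon_edges
    rows = []
    for _, c in cities.iterrows():
        lat_ov = np.clip(np.minimum(lat_e[1:], c.lat_max) - np.maximum(lat_e[:-1], c.lat_min),
                         0.0, None)
        lon_ov = np.clip(np.minimum(lon_e[1:], c.lon_max) - np.maximum(lon_e[:-1], c.lon_min),
                         0.0, None)
        area = np.outer(lat_ov, lon_ov)
        total = area.sum()
        if total <= 0:
            raise ValueError(f"city {c.city_id} does not overlap the grid")
        ii, jj = np.nonzero(area > 0)
        for i, j in zip(ii, jj):
            rows.append({"city_id": c.city_id, "lat_idx": int(i), "lon_idx": int(j),
                         "weight": area[i, j] / total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demography and baseline mortality

# 2050 national scenario ladder: (total-size ratio 2050/2010,
# 65-74 share, >=75 share). 2010 shares are 5.2% / 3.0% (65+ ≈ 8%).
_POP_SCENARIOS_2050 = {
    "S1": (0.970, 0.140, 0.190),
    "S2": (0.960, 0.125, 0.150),
    "S3": (0.995, 0.117, 0.120),
    "S4": (0.944, 0.130, 0.160),
    "S5": (0.965, 0.140, 0.185),
}
_AGE_2010 = {"5-64": 0.852, "65-74": 0.052, "75+": 0.030}  # remainder = under-5
_UNDER5_2050 = 0.035


def generate_population_scenarios(cfg: TruthConfig) -> list[PopulationScenario]:
    """NOCHANGE plus five aging/size scenarios on a shared 2010 city population."""
    rng = _rng(cfg.seed, _STREAM_POP)
    city_ids = [f"city{k:03d}" for k in range(cfg.n_cities)]
    pop_2010 = pd.Series(
        rng.lognormal(mean=math.log(1.6e6), sigma=0.5, size=cfg.n_cities),
        index=city_ids, name="pop_2010")
    scenarios = [
        PopulationScenario(
            scenario_id="NOCHANGE",
            city_pop_2010=pop_2010,
            city_pop_2050=pop_2010.copy(),
            age_fraction_2010=dict(_AGE_2010),
            age_fraction_2050=dict(_AGE_2010),
            rate_ratio={a: (1.0, 1.0, 1.0) for a in AGE_GROUPS},
        )
    ]
    for sid, (ratio, f6574, f75) in _POP_SCENARIOS_2050.items():
        f564 = 1.0 - _UNDER5_2050 - f6574 - f75
        scenarios.append(
            PopulationScenario(
                scenario_id=sid,
                city_pop_2010=pop_2010,
                city_pop_2050=pop_2010 * ratio,
                age_fraction_2010=dict(_AGE_2010),
                age_fraction_2050={"5-64": f564, "65-74": f6574, "75+": f75},
                rate_ratio=dict(DEFAULT_RATE_RATIOS),
            )
        )
    return scenarios


# stratum shares of the all-cause daily mean (anchored to the study's
# reference magnitudes: all-cause 23/day median 18; cardio 11, resp 3;
# ages 5/5/13 of 23 so the >=75 : 5-64 ratio is 2.6; warm:cold 21:20)
_CAUSE_SHARE = {"cardiovascular": 11 / 23, "respiratory": 3 / 23}
_AGE_SHARE = {"5-64": 5 / 23, "65-74": 5 / 23, "75+": 13 / 23}
_WARM_FACTOR = 2 * 21 / 41
_COLD_FACTOR = 2 * 20 / 41


def generate_baseline_mortality(cfg: TruthConfig) -> pd.DataFrame:
    """Per-city baseline mean daily death counts by cause, age group and season.

    Long table ``city_id, stratum_type, stratum, mean_daily_deaths``. All-cause
    city means are lognormal with median 18/day; age-group means sum exactly to
    the all-cause mean and the seasonal means average back to it.
    """
    rng = _rng(cfg.seed, _STREAM_MORT)
    city_ids = [f"city{k:03d}" for k in range(cfg.n_cities)]
    allcause = rng.lognormal(mean=math.log(18.0), sigma=0.7, size=cfg.n_cities)
    rows = []
    for cid, m in zip(city_ids, allcause):
        rows.append((cid, "cause", "non-accidental", m))
        rows.append((cid, "cause", "cardiovascular", m * _CAUSE_SHARE["cardiovascular"]))
        rows.append((cid, "cause", "respiratory", m * _CAUSE_SHARE["respiratory"]))
        for a in AGE_GROUPS:
            rows.append((cid, "age", a, m * _AGE_SHARE[a]))
        rows.append((cid, "season", "warm", m * _WARM_FACTOR))
        rows.append((cid, "season", "cold", m * _COLD_FACTOR))
    return pd.DataFrame(rows, columns=["city_id", "stratum_type", "stratum",
                                       "mean_daily_deaths"])
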