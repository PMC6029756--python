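"""Ozone exposure metrics: MDA8, gridding, city aggregation, summaries.

The exposure metric throughout is the maximum daily 8-hour average (MDA8)
ozone mixing ratio in ppb: the largest running 8-hour mean of the day's
hourly concentrations. A day is usable only if at least 75% of its 24
hourly slots are valid; individual 8-hour windows need at least 6 of 8
valid hours. Missing days are never imputed.

Seasons follow the warm (May–October) / cold (November–April) partition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .grids import GridSpec, grid_of, make_field, make_monthly_field

__all__ = [
    "WARM_MONTHS",
    "COLD_MONTHS",
    "UGM3_PER_PPB",
    "mda8_from_hourly",
    "site_daily_mda8",
    "count_days_in_period",
    "convert_ugm3_to_ppb",
    "grid_site_daily",
    "aggregate_fine_to_coarse",
    "monthly_climatology",
    "city_series_from_grid",
    "exceedance_fraction",
    "period_mean",
]

WARM_MONTHS = frozenset({5, 6, 7, 8, 9, 10})
COLD_MONTHS = frozenset({11, 12, 1, 2, 3, 4})

#: μg/m³ per ppb for ozone at standard reporting conditions (100 μg/m³ ≈ 50 ppb).
UGM3_PER_PPB = 2.0

_N_HOURS = 24
_WINDOW = 8
_MIN_WINDOW_HOURS = 6


def season_mask(months, season: str | None) -> np.ndarray:
    """Boolean mask selecting months of ``season`` ('warm', 'cold', or None=all)."""
    months = np.asarray(months)
    if season is None or season == "annual":
        return np.ones(months.shape, dtype=bool)
    if season == "warm":
        return np.isin(months, list(WARM_MONTHS))
    if season == "cold":
        return np.isin(months, list(COLD_MONTHS))
    raise ValueError(f"unknown season {season!r}")


def mda8_from_hourly(values, completeness_threshold: float = 0.75) -> float:
    """MDA8 for one site-day from up to 24 hourly values (NaN = missing).

    Returns NaN when fewer than ``ceil(24 * completeness_threshold)`` hours
    are valid, or when no 8-hour window has >= 6 valid hours. Windows start
    at local hours 0–16 (no cross-midnight windows); a window's mean is the
    mean of its available hours.
    """
    v = np.full(_N_HOURS, np.nan)
    arr = np.asarray(values, dtype=float)
    if arr.size > _N_HOURS:
        raise ValueError("more than 24 hourly values supplied")
    v[: arr.size] = arr
    present = v[~np.isnan(v)]
    if present.size and present.min() < 0:
        raise ValueError("negative concentration in hourly input")
    out = _mda8_cube(v[None, :], completeness_threshold)
    return float(out[0])


def _mda8_cube(hourly: np.ndarray, completeness_threshold: float = 0.75) -> np.ndarray:
    """Vectorized MDA8 over an (n, 24) array of hourly values."""
    valid = ~np.isnan(hourly)
    min_hours = int(np.ceil(_N_HOURS * completeness_threshold))
    day_ok = valid.sum(axis=1) >= min_hours

    windows = np.lib.stride_tricks.sliding_window_view(hourly, _WINDOW, axis=1)
    w_count = (~np.isnan(windows)).sum(axis=2)
    w_sum = np.nansum(windows, axis=2)
    w_mean = w_sum / np.maximum(w_count, 1)
    w_valid = w_count >= _MIN_WINDOW_HOURS
    out = np.where(w_valid, w_mean, -np.inf).max(axis=1)
    out[~(day_ok & w_valid.any(axis=1))] = np.nan
    return out


def site_daily_mda8(hourly: pd.DataFrame, completeness_threshold: float = 0.75) -> pd.DataFrame:
    """Daily MDA8 per site from a long hourly table.

    ``hourly`` needs columns ``site_id, lat, lon, timestamp, o3_ppb``; absent
    rows are missing hours. Returns a long table
    ``site_id, lat, lon, date, mda8_ppb`` with one row per site-day that has a
    defined MDA8 (days failing the completeness rule are dropped, matching the
    no-imputation convention).
    """
    if (hourly["o3_ppb"] < 0).any():
        raise ValueError("negative concentration in hourly input")
    ts = pd.DatetimeIndex(hourly["timestamp"])
    df = hourly.assign(date=ts.normalize(), hour=ts.hour)

    sites = df[["site_id", "lat", "lon"]].drop_duplicates("site_id").set_index("site_id")
    site_codes, site_ids = pd.factorize(df["site_id"], sort=True)
    dates = pd.DatetimeIndex(sorted(df["date"].unique()))
    date_codes = pd.DatetimeIndex(df["date"]).map({d: k for k, d in enumerate(dates)})

    cube = np.full((len(site_ids), len(dates), _N_HOURS), np.nan)
    cube[site_codes, np.asarray(date_codes), df["hour"].to_numpy()] = df["o3_ppb"].to_numpy()

    mda8 = _mda8_cube(cube.reshape(-1, _N_HOURS), completeness_threshold)
    mda8 = mda8.reshape(len(site_ids), len(dates))
    s_idx, d_idx = np.nonzero(~np.isnan(mda8))
    out = pd.DataFrame(
        {
            "site_id": np.asarray(site_ids)[s_idx],
            "date": dates[d_idx],
            "mda8_ppb": mda8[s_idx, d_idx],
        }
    )
    out["lat"] = sites.loc[out["site_id"], "lat"].to_numpy()
    out["lon"] = sites.loc[out["site_id"], "lon"].to_numpy()
    return out[["site_id", "lat", "lon", "date", "mda8_ppb"]]


def count_days_in_period(start_date, end_date) -> int:
    """Inclusive calendar-day count (Gregorian); e.g. 2013-04-27..2015-10-31 -> 918."""
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if start > end:
        raise ValueError("start_date after end_date")
    return (end.normalize() - start.normalize()).days + 1


def convert_ugm3_to_ppb(value):
    """Convert an ozone mass concentration (μg/m³) to ppb (÷ 2.0)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative concentration")
    out = arr / UGM3_PER_PPB
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def grid_site_daily(site_daily: pd.DataFrame, grid: GridSpec, times=None) -> xr.DataArray:
    """Grid a site-level daily MDA8 table to cell-mean values.

    A cell's value on a day is the unweighted mean of the sites falling in
    that cell with a valid value that day; cells with no reporting site are
    missing. ``times`` fixes the output time axis (default: the dates present).
    """
    i, j = grid.cell_of(site_daily["lat"].to_numpy(), site_daily["lon"].to_numpy())
    if times is None:
        times = pd.DatetimeIndex(sorted(site_daily["date"].unique()))
    else:
        times = pd.DatetimeIndex(times)
    t_map = {d: k for k, d in enumerate(times)}
    t = pd.DatetimeIndex(site_daily["date"]).map(t_map).to_numpy()
    if np.any(pd.isna(t)):
        raise ValueError("site table contains dates outside the requested time axis")
    t = t.astype(int)

    total = np.zeros((len(times), grid.nlat, grid.nlon))
    count = np.zeros_like(total)
    np.add.at(total, (t, i, j), site_daily["mda8_ppb"].to_numpy())
    np.add.at(count, (t, i, j), 1.0)
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.where(count > 0, count, 1), np.nan)
    return make_field(values, times, grid)


def aggregate_fine_to_coarse(field: xr.DataArray, coarse: GridSpec) -> xr.DataArray:
    """Coarse-cell mean of the non-missing nested fine cells (NaN if all missing)."""
    fine = grid_of(field)
    r_lat, r_lon = coarse.nesting_ratio(fine)
    v = field.values.reshape(field.sizes["time"], coarse.nlat, r_lat, coarse.nlon, r_lon)
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out = np.nanmean(v, axis=(2, 4))
    return make_field(out, field["time"].values, coarse)


def _fill_nearest_2d(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor fill of NaN cells (grid-index metric); returns (filled, was_filled)."""
    mask = np.isnan(arr)
    if not mask.any() or mask.all():
        return arr.copy(), mask & ~np.isnan(arr)  # all-NaN stays NaN, nothing filled
    idx = ndimage.distance_transform_edt(mask, return_distances=False, return_indices=True)
    return arr[tuple(idx)], mask


def monthly_climatology(
    field: xr.DataArray, fill: bool = True, return_fill_mask: bool = False
):
    """Per-cell calendar-month means over the field's whole time span.

    Cells with no valid value in a month are filled from the nearest valid
    cell (grid-index nearest neighbor) when ``fill`` is true; the fraction of
    filled cells is recorded in ``attrs['filled_fraction']`` and the mask is
    available via ``return_fill_mask``.
    """
    grid = grid_of(field)
    months = field["time"].dt.month.values
    out = np.full((12, grid.nlat, grid.nlon), np.nan)
    for m in range(1, 13):
        sel = months == m
        if sel.any():
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                out[m - 1] = np.nanmean(field.values[sel], axis=0)
    fill_mask = np.zeros_like(out, dtype=bool)
    if fill:
        for m in range(12):
            if np.isnan(out[m]).any():
                out[m], fill_mask[m] = _fill_nearest_2d(out[m])
    clim = make_monthly_field(out, grid)
    clim.attrs["filled_fraction"] = float(fill_mask.mean())
    if return_fill_mask:
        return clim, fill_mask
    return clim


def city_series_from_grid(field: xr.DataArray, weights: pd.DataFrame) -> pd.DataFrame:
    """City-level daily series as the weighted mean of member grid cells.

    ``weights`` has columns ``city_id, lat_idx, lon_idx, weight`` (per-city
    weights sum to 1). Weights are renormalized over the non-missing member
    cells each day; a day with all member cells missing is missing. Returns a
    wide DataFrame indexed by date with one column per city.
    """
    times = pd.DatetimeIndex(field["time"].values)
    cols = {}
    for city_id, grp in weights.groupby("city_id", sort=True):
        v = field.values[:, grp["lat_idx"].to_numpy(), grp["lon_idx"].to_numpy()]
        w = grp["weight"].to_numpy()
        valid = ~np.isnan(v)
        denom = (valid * w).sum(axis=1)
        numer = np.nansum(v * w, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cols[city_id] = np.where(denom > 0, numer / denom, np.nan)
    return pd.DataFrame(cols, index=times).rename_axis("date")


def exceedance_fraction(series: pd.Series, threshold_ppb: float = 50.0) -> float:
    """Share of non-missing days strictly above ``threshold_ppb``."""
    v = np.asarray(series, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    return float((v > threshold_ppb).mean())


def period_mean(series: pd.Series, season: str | None = None) -> float:
    """Mean over non-missing days restricted to a season ('warm'/'cold'/None)."""
    idx = pd.DatetimeIndex(series.index)
    mask = season_mask(idx.month, season)
    v = np.asarray(series, dtype=float)[mask]
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    return float(v.mean())
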