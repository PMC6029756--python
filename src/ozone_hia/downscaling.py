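"""Bias-correction spatial disaggregation (BCSD) of coarse daily ozone.

The two stages:

1. **Bias correction** (quantile mapping, monthly pooling). For each coarse
   cell and calendar month, empirical quantiles of the historical model and
   observation day pools define an additive bias b(q) = Q_M(q) − Q_O(q) at K
   probability points. A daily value x is placed on the *historical* model
   CDF of its cell-month (so historical monthly biases are assumed to
   persist into the future) and corrected to x − b(q*), with linear
   interpolation in q and constant extrapolation beyond the outer points.

2. **Spatial disaggregation** (additive anomalies). The coarse observed
   monthly climatology is subtracted from the bias-corrected coarse field to
   form daily scaling factors, which are bilinearly interpolated to fine
   cell centers (constant extrapolation beyond the outermost coarse
   centers) and added back to the fine observed monthly climatology.

Concentrations are clamped at 0 ppb after each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GridSpec, grid_of, make_field

__all__ = [
    "QuantileBiasMaps",
    "fit_monthly_quantile_bias",
    "bias_correct_daily",
    "bilinear_weight_matrix",
    "spatial_disaggregate_daily",
    "downscale",
    "DownscaleResult",
]


@dataclass
class QuantileBiasMaps:
    """Per-cell, per-month empirical quantile bias structure.

    Arrays are indexed ``(nlat, nlon, 12, K)``; ``usable`` marks cell-months
    with non-empty model and observation pools. ``bias = model_q − obs_q``.
    """

    grid: GridSpec
    q: np.ndarray
    model_q: np.ndarray
    obs_q: np.ndarray
    usable: np.ndarray

    @property
    def bias(self) -> np.ndarray:
        return self.model_q - self.obs_q

    def to_frame(self) -> pd.DataFrame:
        """Tidy serialization: columns cell lat/lon indices, month, q, Q_M, Q_O, b."""
        nlat, nlon, _, K = self.model_q.shape
        ii, jj, mm, kk = np.meshgrid(np.arange(nlat), np.arange(nlon),
                                     np.arange(12), np.arange(K), indexing="ij")
        df = pd.DataFrame({
            "lat_idx": ii.ravel(), "lon_idx": jj.ravel(), "month": mm.ravel() + 1,
            "q": self.q[kk.ravel()],
            "model_q": self.model_q.ravel(), "obs_q": self.obs_q.ravel(),
            "bias": self.bias.ravel(),
        })
        return df[self.usable[ii.ravel(), jj.ravel(), mm.ravel()]].reset_index(drop=True)


def fit_monthly_quantile_bias(model_hist: xr.DataArray, obs: xr.DataArray,
                              K: int = 99) -> QuantileBiasMaps:
    """Fit monthly quantile bias maps from paired historical coarse fields.

    Days are pooled within each calendar month across all years (monthly, not
    day-by-day matching); pools need not be the same length. Probability
    points are q_k = k/(K+1), k = 1..K, with linear-interpolation empirical
    quantiles. Cell-months where either pool is empty are marked unusable; a
    pool smaller than K/2 triggers a warning.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    grid = grid_of(model_hist)
    if model_hist.shape[1:] != obs.shape[1:]:
        raise ValueError("model and observation fields must share the coarse grid")
    q = np.arange(1, K + 1) / (K + 1)
    nlat, nlon = grid.nlat, grid.nlon
    model_q = np.full((nlat, nlon, 12, K), np.nan)
    obs_q = np.full((nlat, nlon, 12, K), np.nan)
    usable = np.zeros((nlat, nlon, 12), dtype=bool)

    m_months = model_hist["time"].dt.month.values
    o_months = obs["time"].dt.month.values
    small_pools = 0
    for m in range(1, 13):
        mv = model_hist.values[m_months == m]  # (Tm, nlat, nlon)
        ov = obs.values[o_months == m]
        if mv.size == 0 and ov.size == 0:
            continue
        for i in range(nlat):
            for j in range(nlon):
                mp = mv[:, i, j]
                mp = mp[~np.isnan(mp)]
                op = ov[:, i, j]
                op = op[~np.isnan(op)]
                if mp.size == 0 or op.size == 0:
                    continue
                if min(mp.size, op.size) < K / 2:
                    small_pools += 1
                model_q[i, j, m - 1] = np.quantile(mp, q)
                obs_q[i, j, m - 1] = np.quantile(op, q)
                usable[i, j, m - 1] = True
    if small_pools:
        warnings.warn(
            f"{small_pools} cell-month pools smaller than K/2 = {K / 2:.0f} days",
            stacklevel=2)
    return QuantileBiasMaps(grid=grid, q=q, model_q=model_q, obs_q=obs_q, usable=usable)


def bias_correct_daily(fld: xr.DataArray, maps: QuantileBiasMaps) -> xr.DataArray:
    """Quantile-map a coarse daily field using fitted historical bias maps.

    Each value is positioned on its cell-month's historical model CDF, the
    bias at that quantile (linearly interpolated, constant beyond the outer
    probability points) is subtracted, and the result is clamped at 0 ppb.
    Values in unusable cell-months become missing.
    """
    grid = grid_of(fld)
    if (grid.nlat, grid.nlon) != (maps.grid.nlat, maps.grid.nlon):
        raise ValueError("field grid does not match fitted maps")
    months = fld["time"].dt.month.values
    out = np.full(fld.shape, np.nan)
    for m in range(1, 13):
        t_sel = months == m
        if not t_sel.any():
            continue
        for i in range(grid.nlat):
            for j in range(grid.nlon):
                x = fld.values[t_sel, i, j]
                if not maps.usable[i, j, m - 1]:
                    continue
                mq = maps.model_q[i, j, m - 1]
                b = maps.bias[i, j, m - 1]
                # CDF position on the historical model pool; np.interp is
                # constant beyond [mq[0], mq[-1]], matching constant-tail b
                qstar = np.interp(x, mq, maps.q)
                corr = x - np.interp(qstar, maps.q, b)
                out[t_sel, i, j] = np.maximum(corr, 0.0)
        # propagate input missingness
    out[np.isnan(fld.values)] = np.nan
    return make_field(out, fld["time"].values, grid)


def bilinear_weight_matrix(coarse: GridSpec, fine: GridSpec) -> np.ndarray:
    """Dense (fine_cells × coarse_cells) bilinear interpolation matrix.

    Interpolates values at coarse cell centers to fine cell centers; fine
    centers beyond the outermost coarse centers use constant (clamped)
    extrapolation. Row-major flattening (lat, lon) on both grids.
    """
    clat, clon = coarse.lat_centers, coarse.lon_centers
    flat = np.clip(fine.lat_centers, clat[0], clat[-1])
    flon = np.clip(fine.lon_centers, clon[0], clon[-1])

    def _axis_weights(targets, centers):
        if len(centers) == 1:
            return np.zeros(len(targets), dtype=int), np.zeros(len(targets))
        i = np.clip(np.searchsorted(centers, targets, side="right") - 1,
                    0, len(centers) - 2)
        frac = (targets - centers[i]) / (centers[i + 1] - centers[i])
        return i, frac

    ilat, wlat = _axis_weights(flat, clat)
    ilon, wlon = _axis_weights(flon, clon)
    A = np.zeros((fine.nlat * fine.nlon, coarse.nlat * coarse.nlon))
    for fi in range(fine.nlat):
        for fj in range(fine.nlon):
            r = fi * fine.nlon + fj
            i0, a = ilat[fi], wlat[fi]
            j0, b = ilon[fj], wlon[fj]
            i1 = min(i0 + 1, coarse.nlat - 1)
            j1 = min(j0 + 1, coarse.nlon - 1)
            A[r, i0 * coarse.nlon + j0] += (1 - a) * (1 - b)
            A[r, i0 * coarse.nlon + j1] += (1 - a) * b
            A[r, i1 * coarse.nlon + j0] += a * (1 - b)
            A[r, i1 * coarse.nlon + j1] += a * b
    return A


def spatial_disaggregate_daily(corrected: xr.DataArray, obs_clim_coarse: xr.DataArray,
                               obs_clim_fine: xr.DataArray,
                               fine: GridSpec | None = None) -> xr.DataArray:
    """Disaggregate a bias-corrected coarse daily field to the fine grid.

    Daily scaling factors S = corrected − coarse observed climatology (by
    calendar month) are bilinearly interpolated to fine cell centers and the
    fine observed climatology is added back; output is clamped at 0 ppb.
    Coarse cells with missing anomalies poison exactly the fine cells that
    draw weight from them.
    """
    coarse = grid_of(corrected)
    if fine is None:
        fine = grid_of(obs_clim_fine)
    months = corrected["time"].dt.month.values
    S = corrected.values - obs_clim_coarse.values[months - 1]  # (T, nlat_c, nlon_c)
    T = S.shape[0]
    S2 = S.reshape(T, -1)
    A = bilinear_weight_matrix(coarse, fine)

    bad = np.isnan(S2)
    S2_filled = np.where(bad, 0.0, S2)
    S_fine = S2_filled @ A.T
    poisoned = bad.astype(float) @ (A.T > 0)
    S_fine[poisoned > 0] = np.nan
    S_fine = S_fine.reshape(T, fine.nlat, fine.nlon)

    clim_f = obs_clim_fine.values[months - 1]
    out = np.maximum(S_fine + clim_f, 0.0)
    out[np.isnan(S_fine) | np.isnan(clim_f)] = np.nan
    return make_field(out, corrected["time"].values, fine)


@dataclass
class DownscaleResult:
    """Bias-corrected and disaggregated fields plus per-stage diagnostics."""

    hist_corrected_coarse: xr.DataArray
    future_corrected_coarse: xr.DataArray
    hist_fine: xr.DataArray
    future_fine: xr.DataArray
    maps: QuantileBiasMaps
    diagnostics: dict = field(default_factory=dict)


def _mean_diff(a: xr.DataArray, b: xr.DataArray) -> float:
    d = a.values - b.values
    return float(np.nanmean(d))


def downscale(model_hist: xr.DataArray, model_future: xr.DataArray,
              obs_coarse_daily: xr.DataArray, obs_clim_coarse: xr.DataArray,
              obs_clim_fine: xr.DataArray, K: int = 99) -> DownscaleResult:
    """Run the full BCSD chain for one scenario/ensemble member.

    Fits monthly quantile bias maps on the historical pair, corrects both
    periods, disaggregates both to the fine grid, and reports diagnostics:
    mean bias before/after correction and per-month RMSE between corrected
    historical quantiles and observed quantiles.
    """
    maps = fit_monthly_quantile_bias(model_hist, obs_coarse_daily, K=K)
    hist_corr = bias_correct_daily(model_hist, maps)
    fut_corr = bias_correct_daily(model_future, maps)
    hist_fine = spatial_disaggregate_daily(hist_corr, obs_clim_coarse, obs_clim_fine)
    fut_fine = spatial_disaggregate_daily(fut_corr, obs_clim_coarse, obs_clim_fine)

    corr_maps = fit_monthly_quantile_bias(hist_corr, obs_coarse_daily, K=K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        qrmse = np.sqrt(np.nanmean((corr_maps.model_q - corr_maps.obs_q) ** 2,
                                   axis=(0, 1, 3)))
    diagnostics = {
        "mean_bias_before_ppb": _mean_diff(model_hist, obs_coarse_daily),
        "mean_bias_after_ppb": _mean_diff(hist_corr, obs_coarse_daily),
        "monthly_quantile_rmse_ppb": qrmse,
    }
    return DownscaleResult(hist_corr, fut_corr, hist_fine, fut_fine, maps, diagnostics)
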