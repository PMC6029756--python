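"""Regular latitude–longitude grid specifications and gridded-field helpers.

Fields are plain :class:`xarray.DataArray` objects with dims ``(time, lat, lon)``
(or ``(month, lat, lon)`` for climatologies); coordinates hold cell *centers*.
A :class:`GridSpec` describes the cell geometry so that nesting, aggregation and
interpolation between a coarse grid (e.g. 2.0° × 2.5°) and a fine grid
(e.g. 0.25° × 0.25°) are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["GridSpec", "make_field", "make_monthly_field", "grid_of"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lat–lon grid: origin is the lower-left (south-west) *corner*."""

    lat0: float
    lon0: float
    dlat: float
    dlon: float
    nlat: int
    nlon: int

    def __post_init__(self) -> None:
        if self.dlat <= 0 or self.dlon <= 0 or self.nlat < 1 or self.nlon < 1:
            raise ValueError("grid spec requires positive cell sizes and counts")

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.nlat) + 0.5) * self.dlat

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.nlon) + 0.5) * self.dlon

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat0 + np.arange(self.nlat + 1) * self.dlat

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon0 + np.arange(self.nlon + 1) * self.dlon

    @property
    def lat_max(self) -> float:
        return self.lat0 + self.nlat * self.dlat

    @property
    def lon_max(self) -> float:
        return self.lon0 + self.nlon * self.dlon

    @property
    def ncells(self) -> int:
        return self.nlat * self.nlon

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat)
        lon = np.asarray(lon)
        return (
            (lat >= self.lat0)
            & (lat <= self.lat_max)
            & (lon >= self.lon0)
            & (lon <= self.lon_max)
        )

    def cell_of(self, lat, lon) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of the cell containing each point.

        Points on the outer boundary are assigned to the last cell.
        Raises ``ValueError`` for points outside the grid extent.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if not np.all(self.contains(lat, lon)):
            raise ValueError("point(s) outside grid extent")
        i = np.minimum(((lat - self.lat0) / self.dlat).astype(int), self.nlat - 1)
        j = np.minimum(((lon - self.lon0) / self.dlon).astype(int), self.nlon - 1)
        return i, j

    def nesting_ratio(self, fine: "GridSpec") -> tuple[int, int]:
        """Integer (lat, lon) refinement ratio of ``fine`` within ``self``.

        Requires aligned origins/extents and an integer number of fine cells
        per coarse cell in each direction.
        """
        r_lat = self.dlat / fine.dlat
        r_lon = self.dlon / fine.dlon
        ok = (
            abs(r_lat - round(r_lat)) < 1e-9
            and abs(r_lon - round(r_lon)) < 1e-9
            and abs(self.lat0 - fine.lat0) < 1e-9
            and abs(self.lon0 - fine.lon0) < 1e-9
            and fine.nlat == self.nlat * round(r_lat)
            and fine.nlon == self.nlon * round(r_lon)
        )
        if not ok:
            raise ValueError("fine grid does not nest in coarse grid")
        return round(r_lat), round(r_lon)


def make_field(values: np.ndarray, times, grid: GridSpec, units: str = "ppb") -> xr.DataArray:
    """Wrap a (time, lat, lon) array as a coordinate-carrying DataArray."""
    values = np.asarray(values, dtype=float)
    times = pd.DatetimeIndex(times)
    if values.shape != (len(times), grid.nlat, grid.nlon):
        raise ValueError(
            f"values shape {values.shape} does not match "
            f"({len(times)}, {grid.nlat}, {grid.nlon})"
        )
    return xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={"time": times, "lat": grid.lat_centers, "lon": grid.lon_centers},
        name="mda8_o3",
        attrs={"units": units, "dlat": grid.dlat, "dlon": grid.dlon,
               "lat0": grid.lat0, "lon0": grid.lon0},
    )


def make_monthly_field(values: np.ndarray, grid: GridSpec, units: str = "ppb") -> xr.DataArray:
    """Wrap a (12, lat, lon) climatology array (months 1..12)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (12, grid.nlat, grid.nlon):
        raise ValueError("climatology must have shape (12, nlat, nlon)")
    return xr.DataArray(
        values,
        dims=("month", "lat", "lon"),
        coords={"month": np.arange(1, 13), "lat": grid.lat_centers, "lon": grid.lon_centers},
        name="mda8_o3_clim",
        attrs={"units": units, "dlat": grid.dlat, "dlon": grid.dlon,
               "lat0": grid.lat0, "lon0": grid.lon0},
    )


def grid_of(field: xr.DataArray) -> GridSpec:
    """Recover the :class:`GridSpec` of a field built by this module."""
    a = field.attrs
    if "dlat" in a:
        return GridSpec(a["lat0"], a["lon0"], a["dlat"], a["dlon"],
                        field.sizes["lat"], field.sizes["lon"])
    # fall back to coordinate spacing (fields read back from disk keep attrs,
    # but hand-built test fields may not)
    lat = np.asarray(field["lat"])
    lon = np.asarray(field["lon"])
    dlat = float(lat[1] - lat[0]) if lat.size > 1 else 1.0
    dlon = float(lon[1] - lon[0]) if lon.size > 1 else 1.0
    return GridSpec(float(lat[0]) - dlat / 2, float(lon[0]) - dlon / 2,
                    dlat, dlon, lat.size, lon.size)
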