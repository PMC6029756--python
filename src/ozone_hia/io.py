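"""File I/O: NetCDF gridded fields, CSV tables, and the run manifest.

Gridded daily fields are written as CF-style NetCDF (dimensions time/lat/
lon, variable ``mda8_o3`` in ppb) through xarray's scipy backend; tabular
artifacts are plain CSV. A run manifest (YAML) records the config, the
adopted numerical conventions, and a SHA-256 inventory of every output file
so a run can be re-checked bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import xarray as xr
import yaml

from .metrics import UGM3_PER_PPB

__all__ = ["write_field", "read_field", "write_table", "read_table",
           "build_manifest", "save_result_bundle"]

_CONVENTIONS = {
    "ugm3_per_ppb": UGM3_PER_PPB,
    "percentile_rule": "linear interpolation between order statistics",
    "annualization": "sum of ADD over covered days / (covered days / 365.25)",
    "mda8_windows": "17 windows starting hours 0-16; >=6/8 valid hours; day needs >=18/24",
}


def write_field(field: xr.DataArray, path) -> Path:
    path = Path(path)
    field = field.copy()
    field.attrs.setdefault("units", "ppb")
    ds = field.to_dataset(name=field.name or "mda8_o3")
    ds.to_netcdf(path, engine="scipy")
    return path


def read_field(path, name: str = "mda8_o3") -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds[name].load()


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, index=index)
    return path


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(out_dir, config_dict: dict, extra: dict | None = None) -> dict:
    """Manifest of a run directory: config hash, conventions, file checksums."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.yaml")
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest(),
        "conventions": dict(_CONVENTIONS),
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest


def save_result_bundle(result, out_dir) -> dict:
    """Write an :class:`~ozone_hia.pipeline.ExperimentResult` to a directory."""
    from .config import config_to_dict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(result.summary, out / "summary.csv")
    write_table(result.seasonal, out / "seasonal.csv")
    write_table(result.decomposition, out / "decomposition.csv")
    write_table(result.assessment, out / "assessment.csv")
    write_table(result.baseline, out / "baseline_mortality.csv")
    write_table(result.crfs, out / "crf_table.csv")
    write_table(result.cities, out / "cities.csv")
    write_table(result.sites, out / "sites.csv")
    write_table(result.weights_fine, out / "city_weights_fine.csv")
    write_table(result.weights_coarse, out / "city_weights_coarse.csv")
    result.hist_exposure.to_csv(out / "exposure_historical.csv")
    for (rcp, member), df in result.future_exposures.items():
        df.to_csv(out / f"exposure_future_{rcp}_m{member}.csv")
    with open(out / "diagnostics.yaml", "w") as fh:
        yaml.safe_dump({k: float(v) for k, v in result.diagnostics.items()}, fh)
    return build_manifest(out, config_to_dict(result.config))
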