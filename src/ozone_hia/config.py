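"""Structured YAML configuration for the experiment pipeline.

One config file drives every stage; the defaults reproduce the design
dimensions of the study conditions (918-day periods, 2 emission scenarios,
6 population scenarios, 3 ensemble members, 1,000 draws, warm/cold split).
Schema violations are reported with the offending field path.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .grids import GridSpec
from .pipeline import ExperimentConfig
from .synthetic import BiasProfile, TruthConfig

__all__ = ["ConfigError", "load_config", "config_to_dict", "dump_config"]


class ConfigError(ValueError):
    """A configuration schema violation, with the field path in the message."""


def _check(mapping, path: str, allowed: set[str]) -> None:
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown field(s) {sorted(unknown)}")


def _grid(d: dict, path: str) -> GridSpec:
    _check(d, path, {"lat0", "lon0", "dlat", "dlon", "nlat", "nlon"})
    try:
        return GridSpec(**{k: (int(v) if k.startswith("n") else float(v))
                           for k, v in d.items()})
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: {err}") from err


def _truth(d: dict) -> TruthConfig:
    allowed = {f.name for f in dataclasses.fields(TruthConfig)}
    _check(d, "truth", allowed)
    kwargs = dict(d)
    for key in ("coarse_grid", "fine_grid"):
        if key in kwargs:
            kwargs[key] = _grid(kwargs[key], f"truth.{key}")
    for key in ("historical_period", "future_period"):
        if key in kwargs:
            v = kwargs[key]
            if not (isinstance(v, (list, tuple)) and len(v) == 2):
                raise ConfigError(f"truth.{key}: expected [start, end]")
            kwargs[key] = (str(v[0]), str(v[1]))
    if "bias_profile" in kwargs:
        bp = kwargs["bias_profile"]
        _check(bp, "truth.bias_profile", {"kind", "mean", "slope"})
        kwargs["bias_profile"] = BiasProfile(**bp)
    try:
        return TruthConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"truth: {err}") from err


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _check(raw, "<root>", {"truth", "experiment"})
    truth = _truth(raw.get("truth", {}))
    exp = raw.get("experiment", {})
    _check(exp, "experiment",
           {"n_draws", "quantile_points", "exceedance_threshold_ppb", "scenarios"})
    if "scenarios" in exp:
        exp["scenarios"] = tuple(exp["scenarios"])
    try:
        return ExperimentConfig(truth=truth, **exp)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"experiment: {err}") from err


def config_to_dict(config: ExperimentConfig) -> dict:
    """Round-trippable plain-dict form of a config (for manifests / YAML)."""
    t = config.truth
    return {
        "truth": {
            "seed": t.seed, "n_sites": t.n_sites, "n_cities": t.n_cities,
            "coarse_grid": dataclasses.asdict(t.coarse_grid),
            "fine_grid": dataclasses.asdict(t.fine_grid),
            "historical_period": list(t.historical_period),
            "future_period": list(t.future_period),
            "bias_profile": dataclasses.asdict(t.bias_profile),
            "trend_profile": {k: dict(v) for k, v in t.trend_profile.items()},
            "missing_rate": t.missing_rate, "n_ensemble": t.n_ensemble,
        },
        "experiment": {
            "n_draws": config.n_draws,
            "quantile_points": config.quantile_points,
            "exceedance_threshold_ppb": config.exceedance_threshold_ppb,
            "scenarios": list(config.scenarios),
        },
    }


def dump_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
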