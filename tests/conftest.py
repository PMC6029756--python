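import numpy as np
import pandas as pd
import pytest

from ozone_hia.grids import GridSpec, make_field
from ozone_hia.pipeline import ExperimentConfig, run_experiment
from ozone_hia.synthetic import TruthConfig


@pytest.fixture(scope="session")
def tiny_truth() -> TruthConfig:
    """One-year periods, small domain: fast but spans both seasons."""
    return TruthConfig(
        seed=3, n_sites=14, n_cities=3,
        coarse_grid=GridSpec(30.0, 110.0, 2.0, 2.5, 2, 2),
        fine_grid=GridSpec(30.0, 110.0, 0.25, 0.25, 16, 20),
        historical_period=("2013-05-01", "2014-04-30"),
        future_period=("2053-05-01", "2054-04-30"),
    )


@pytest.fixture(scope="session")
def tiny_result(tiny_truth):
    """A full experiment on the tiny config, shared across test modules.

    One-year periods give ~30-day cell-month pools, so the quantile grid is
    sized accordingly (the 918-day default uses K=99 on ~77-day pools).
    """
    return run_experiment(ExperimentConfig(truth=tiny_truth, n_draws=40,
                                           quantile_points=29))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def constant_field(value, grid: GridSpec, dates) -> "pd.DataFrame":
    times = pd.date_range(*dates) if isinstance(dates, tuple) else dates
    return make_field(np.full((len(times), grid.nlat, grid.nlon), float(value)),
                      times, grid)


@pytest.fixture()
def small_grid() -> GridSpec:
    return GridSpec(30.0, 110.0, 2.0, 2.5, 2, 2)


@pytest.fixture()
def small_fine_grid() -> GridSpec:
    return GridSpec(30.0, 110.0, 0.25, 0.25, 16, 20)
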