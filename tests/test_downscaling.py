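"""BCSD: quantile bias mapping, correction, and anomaly disaggregation."""

import numpy as np
import pandas as pd
import pytest

from ozone_hia.grids import GridSpec, make_field, make_monthly_field
from ozone_hia import downscaling as dsc
from ozone_hia import metrics
from ozone_hia import synthetic as syn


GRID = GridSpec(30.0, 110.0, 2.0, 2.5, 2, 2)
TIMES = pd.date_range("2013-01-01", "2016-12-31")


def _field(values):
    return make_field(values, TIMES, GRID)


def _random_pair(rng, scale=1.3, shift=10.0):
    """Heteroscedastic synthetic model/obs pair on the shared grid."""
    base = 40 + 10 * np.sin(2 * np.pi * TIMES.dayofyear.to_numpy() / 365.25)
    obs = base[:, None, None] + rng.normal(0, 6, size=(len(TIMES), 2, 2))
    model = shift + base[:, None, None] * scale + rng.normal(0, 9, size=obs.shape)
    return _field(np.maximum(model, 0)), _field(np.maximum(obs, 0))


class TestFitQuantileBias:
    def test_identical_fields_give_zero_bias(self, rng):
        model, obs = _random_pair(rng)
        maps = dsc.fit_monthly_quantile_bias(model, model, K=19)
        assert np.allclose(maps.bias[maps.usable], 0.0)

    def test_additive_shift_moves_every_quantile(self, rng):
        _, obs = _random_pair(rng)
        shifted = _field(obs.values + 17.0)
        maps = dsc.fit_monthly_quantile_bias(shifted, obs, K=19)
        assert np.allclose(maps.bias[maps.usable], 17.0)

    def test_matches_sorted_sample_oracle(self, rng):
        model, obs = _random_pair(rng)
        K = 19
        maps = dsc.fit_monthly_quantile_bias(model, obs, K=K)
        q = np.arange(1, K + 1) / (K + 1)
        months = TIMES.month.to_numpy()
        for m in (1, 7):
            mp = model.values[months == m, 0, 1]
            op = obs.values[months == m, 0, 1]
            want = np.quantile(mp, q) - np.quantile(op, q)
            np.testing.assert_allclose(maps.bias[0, 1, m - 1], want)

    def test_empty_obs_pool_marked_unusable(self, rng):
        model, obs = _random_pair(rng)
        v = obs.values.copy()
        v[:, 1, 1] = np.nan
        maps = dsc.fit_monthly_quantile_bias(model, _field(v), K=9)
        assert not maps.usable[1, 1].any()
        assert maps.usable[0, 0].all()

    def test_small_k_rejected(self, rng):
        model, obs = _random_pair(rng)
        with pytest.raises(ValueError):
            dsc.fit_monthly_quantile_bias(model, obs, K=1)


class TestBiasCorrect:
    def test_zero_bias_is_identity(self, rng):
        model, _ = _random_pair(rng)
        maps = dsc.fit_monthly_quantile_bias(model, model, K=49)
        out = dsc.bias_correct_daily(model, maps)
        np.testing.assert_allclose(out.values, model.values, atol=1e-9)

    def test_constant_bias_subtracts(self, rng):
        _, obs = _random_pair(rng)
        shifted = _field(obs.values + 17.0)
        maps = dsc.fit_monthly_quantile_bias(shifted, obs, K=49)
        out = dsc.bias_correct_daily(shifted, maps)
        np.testing.assert_allclose(out.values, np.maximum(obs.values, 0), atol=1e-6)

    def test_fixed_point_exact_at_quantile_knots(self, rng):
        """A day whose value sits exactly on a model quantile knot is mapped
        exactly onto the corresponding observed quantile."""
        model, obs = _random_pair(rng)
        K = 49
        maps = dsc.fit_monthly_quantile_bias(model, obs, K=K)
        for m, (i, j) in ((1, (0, 0)), (7, (1, 1))):
            knots = maps.model_q[i, j, m - 1]
            n = len(knots)
            month_dates = pd.date_range(f"2013-{m:02d}-01", periods=min(n, 28))
            fld = make_field(
                np.tile(knots[: len(month_dates), None, None], (1, 2, 2)),
                month_dates, GRID)
            out = dsc.bias_correct_daily(fld, maps)
            np.testing.assert_allclose(
                out.values[:, i, j],
                np.maximum(maps.obs_q[i, j, m - 1][: len(month_dates)], 0.0),
                atol=1e-9)

    def test_fixed_point_distributional(self, rng):
        """Correcting the historical model by its own maps reproduces the
        observed quantiles at every probability point (within pool spacing)."""
        model, obs = _random_pair(rng)
        K = 49
        maps = dsc.fit_monthly_quantile_bias(model, obs, K=K)
        corrected = dsc.bias_correct_daily(model, maps)
        remaps = dsc.fit_monthly_quantile_bias(corrected, obs, K=K)
        resid = remaps.model_q[remaps.usable] - remaps.obs_q[remaps.usable]
        assert np.max(np.abs(resid)) < 1.5
        assert np.mean(np.abs(resid)) < 0.3

    def test_monotone_in_input(self, rng):
        # monotonicity holds within a cell-month: keep all days in July
        model, obs = _random_pair(rng)
        maps = dsc.fit_monthly_quantile_bias(model, obs, K=49)
        x = np.sort(rng.uniform(0, 120, size=31))
        fld = make_field(np.tile(x[:, None, None], (1, 2, 2)),
                         pd.date_range("2013-07-01", periods=31), GRID)
        out = dsc.bias_correct_daily(fld, maps)
        col = out.values[:, 0, 0]
        assert np.all(np.diff(col) >= -1e-9)

    def test_unusable_cell_yields_missing(self, rng):
        model, obs = _random_pair(rng)
        v = obs.values.copy()
        v[:, 1, 1] = np.nan
        maps = dsc.fit_monthly_quantile_bias(model, _field(v), K=9)
        out = dsc.bias_correct_daily(model, maps)
        assert np.isnan(out.values[:, 1, 1]).all()
        assert not np.isnan(out.values[:, 0, 0]).any()

    def test_future_additive_shift_preserved_under_constant_bias(self, rng):
        """With a flat quantile bias, a uniform future shift passes through."""
        _, obs = _random_pair(rng)
        model = _field(obs.values + 17.0)
        maps = dsc.fit_monthly_quantile_bias(model, obs, K=49)
        future = _field(model.values + 6.5)
        out_f = dsc.bias_correct_daily(future, maps)
        out_h = dsc.bias_correct_daily(model, maps)
        np.testing.assert_allclose(out_f.values - out_h.values, 6.5, atol=1e-6)


FINE = GridSpec(30.0, 110.0, 0.25, 0.25, 16, 20)


def _clims(coarse_vals, fine_vals):
    cc = make_monthly_field(np.tile(coarse_vals, (12, 1, 1)), GRID)
    cf = make_monthly_field(np.tile(fine_vals, (12, 1, 1)), FINE)
    return cc, cf


class TestDisaggregate:
    def test_uniform_everything_passes_through(self):
        times = pd.date_range("2014-06-01", periods=4)
        corrected = make_field(np.full((4, 2, 2), 47.0), times, GRID)
        cc, cf = _clims(np.full((2, 2), 30.0), np.full((16, 20), 30.0))
        out = dsc.spatial_disaggregate_daily(corrected, cc, cf)
        assert np.allclose(out.values, 47.0)

    def test_zero_anomaly_returns_fine_climatology(self, rng):
        times = pd.date_range("2014-06-01", periods=2)
        coarse_clim = rng.uniform(20, 60, size=(2, 2))
        fine_clim = rng.uniform(20, 60, size=(16, 20))
        corrected = make_field(np.tile(coarse_clim, (2, 1, 1)), times, GRID)
        cc, cf = _clims(coarse_clim, fine_clim)
        out = dsc.spatial_disaggregate_daily(corrected, cc, cf)
        for t in range(2):
            np.testing.assert_allclose(out.values[t], fine_clim)

    def test_linear_anomaly_interpolates_exactly(self):
        """A linear-in-longitude anomaly is reproduced exactly by bilinear
        interpolation between coarse centers (constant beyond the edges)."""
        times = pd.date_range("2014-06-01", periods=1)
        clon = GRID.lon_centers
        anomaly = np.array([[2.0 * (c - clon[0]) for c in clon]] * 2)  # (2,2)
        corrected = make_field(anomaly[None] + 30.0, times, GRID)
        cc, cf = _clims(np.full((2, 2), 30.0), np.full((16, 20), 30.0))
        out = dsc.spatial_disaggregate_daily(corrected, cc, cf)
        flon = np.clip(FINE.lon_centers, clon[0], clon[-1])
        want = 30.0 + 2.0 * (flon - clon[0])
        for row in range(16):
            np.testing.assert_allclose(out.values[0, row, :], want, atol=1e-12)

    def test_missing_anomaly_poisons_dependent_cells_only(self):
        times = pd.date_range("2014-06-01", periods=1)
        vals = np.full((1, 2, 2), 40.0)
        vals[0, 1, 1] = np.nan
        corrected = make_field(vals, times, GRID)
        cc, cf = _clims(np.full((2, 2), 30.0), np.full((16, 20), 30.0))
        out = dsc.spatial_disaggregate_daily(corrected, cc, cf)
        assert np.isnan(out.values[0, -1, -1])     # inside the missing cell
        assert not np.isnan(out.values[0, 0, 0])   # far corner unaffected


@pytest.fixture(scope="module")
def cfg():
    return syn.TruthConfig(
        seed=21, n_sites=12, n_cities=3,
        coarse_grid=GRID, fine_grid=FINE,
        historical_period=("2013-05-01", "2014-04-30"),
        future_period=("2053-05-01", "2054-04-30"))


@pytest.fixture(scope="module")
def obs_products(cfg):
    obs = syn.generate_site_hourly_obs(cfg)
    daily = metrics.site_daily_mda8(obs)
    fine = metrics.grid_site_daily(daily, cfg.fine_grid,
                                   times=cfg.dates("historical"))
    coarse = metrics.aggregate_fine_to_coarse(fine, cfg.coarse_grid)
    return fine, coarse, metrics.monthly_climatology(fine), \
        metrics.monthly_climatology(coarse)


class TestDownscaleChain:
    def test_perfect_model_identity(self, cfg, obs_products):
        """model == observations -> the whole chain is the identity up to
        interpolation tolerance (daily anomalies are spatially uniform)."""
        fine, coarse, clim_f, clim_c = obs_products
        with np.errstate(invalid="ignore"):
            res = dsc.downscale(coarse, coarse, coarse, clim_c, clim_f, K=49)
        assert abs(res.diagnostics["mean_bias_before_ppb"]) < 1e-9
        assert abs(res.diagnostics["mean_bias_after_ppb"]) < 0.05
        # city-scale closure of the fine output against the gridded obs
        w = syn.generate_city_geometry_weights(cfg)
        got = metrics.city_series_from_grid(res.hist_fine, w)
        want = metrics.city_series_from_grid(fine, w)
        diff = (got - want).mean()
        assert np.abs(diff.to_numpy()).max() < 1.0

    def test_injected_bias_reported_and_removed(self, cfg, obs_products):
        _, coarse, clim_f, clim_c = obs_products
        model = syn.generate_coarse_model_daily(cfg, "rcp85", 1)
        res = dsc.downscale(model["historical"], model["future"], coarse,
                            clim_c, clim_f, K=49)
        assert res.diagnostics["mean_bias_before_ppb"] == pytest.approx(17.0, abs=1.0)
        assert abs(res.diagnostics["mean_bias_after_ppb"]) < 0.5

    def test_future_fine_tracks_truth_plus_trend(self, cfg, obs_products):
        _, coarse, clim_f, clim_c = obs_products
        model = syn.generate_coarse_model_daily(cfg, "rcp85", 1)
        res = dsc.downscale(model["historical"], model["future"], coarse,
                            clim_c, clim_f, K=49)
        w = syn.generate_city_geometry_weights(cfg)
        got = metrics.city_series_from_grid(res.future_fine, w)
        truth = syn.truth_city_series(cfg, w, cfg.fine_grid, "future", "rcp85")
        # period-mean closure per city against the latent truth + trend
        diff = got.mean() - truth.mean()
        assert np.abs(diff.to_numpy()).max() < 2.0

    def test_climatology_closure(self, cfg, obs_products):
        """Monthly means of the disaggregated historical-corrected field match
        the fine observed climatology."""
        fine, coarse, clim_f, clim_c = obs_products
        model = syn.generate_coarse_model_daily(cfg, "rcp45", 1)
        res = dsc.downscale(model["historical"], model["future"], coarse,
                            clim_c, clim_f, K=49)
        out_clim = metrics.monthly_climatology(res.hist_fine, fill=False)
        diff = out_clim.values - clim_f.values
        assert abs(np.nanmean(diff)) < 0.5
        assert np.nanmax(np.abs(diff)) < 4.0
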