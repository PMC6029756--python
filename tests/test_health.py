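"""Attributable-fraction health impact machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ozone_hia import health as h
from ozone_hia.synthetic import AGE_GROUPS, PopulationScenario


class TestBeta:
    def test_zero_percent_gives_zero(self):
        assert h.beta_from_percent(0.0) == 0.0

    def test_reference_value(self):
        # 0.24% per 10 μg/m³ (≈5 ppb): β = ln(1.0024)/5
        assert h.beta_from_percent(0.24) == pytest.approx(np.log(1.0024) / 5.0)

    def test_age_crf_ratio_near_3_2(self):
        ratio = h.beta_from_percent(0.42) / h.beta_from_percent(0.13)
        assert ratio == pytest.approx(3.23, abs=0.01)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            h.beta_from_percent(-100.0)


class TestAttributableFraction:
    def test_zero_limits(self):
        assert h.attributable_fraction(0.0, 50.0) == 0.0
        assert h.attributable_fraction(0.01, 0.0) == 0.0

    def test_reference_value(self):
        beta = h.beta_from_percent(0.24)
        # 1 − 1.0024^−10 at 50 ppb
        assert h.attributable_fraction(beta, 50.0) == pytest.approx(0.0236862, abs=2e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            h.attributable_fraction(0.001, -5.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 100), st.floats(0.01, 0.5))
    def test_bounds_and_no_threshold(self, conc, pct):
        af = h.attributable_fraction(h.beta_from_percent(pct), conc)
        assert 0.0 <= af < 1.0
        if conc > 0:
            assert af > 0.0  # no threshold below which risk vanishes

    @pytest.mark.parametrize("pct", [0.24, 0.27, 0.18, 0.13, 0.19, 0.42, 0.20, 0.43])
    def test_linearization_bound_for_default_crfs(self, pct):
        beta = h.beta_from_percent(pct)
        for c in np.linspace(0.0, 100.0, 21):
            af = h.attributable_fraction(beta, c)
            assert abs(af - beta * c) <= (beta * c) ** 2 / 2 + 1e-15


class TestADDAndAnnualization:
    def test_add_is_product(self):
        assert h.attributable_daily_deaths(23.0, 0.02) == pytest.approx(0.46)
        assert h.attributable_daily_deaths(0.0, 0.5) == 0.0
        assert h.attributable_daily_deaths(23.0, 0.0) == 0.0

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            h.attributable_daily_deaths(-1.0, 0.1)

    def test_constant_add_annualizes_to_yearly_total(self):
        assert h.annualize(np.full(918, 0.5)) == pytest.approx(365.25 * 0.5)

    def test_missing_days_excluded_from_time_base(self):
        v = np.full(918, 0.5)
        v[::2] = np.nan
        assert h.annualize(v) == pytest.approx(365.25 * 0.5)

    def test_matches_brute_force_on_seasonal_series(self, rng):
        v = np.abs(np.sin(np.arange(918) / 58.0)) * rng.uniform(0.5, 1.5, 918)
        v[rng.random(918) < 0.1] = np.nan
        covered = v[~np.isnan(v)]
        want = covered.sum() / (covered.size / 365.25)
        assert h.annualize(v) == pytest.approx(want)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            h.annualize(np.full(10, np.nan))

    def test_vectorized_draws_match_scalar_path(self, rng):
        idx = pd.date_range("2013-01-01", periods=365)
        c = pd.Series(rng.uniform(10, 90, 365), index=idx)
        betas = np.array([0.0002, 0.0005, 0.001])
        vec = h.annual_attributable(c, 7.0, betas)
        for k, b in enumerate(betas):
            af = h.attributable_fraction(b, c.to_numpy())
            scalar = h.annualize(h.attributable_daily_deaths(7.0, af))
            assert vec[k] == pytest.approx(scalar)

    def test_lag_window_near_invariant_for_annual_sums(self, rng):
        idx = pd.date_range("2013-01-01", "2014-12-31")
        c = pd.Series(45 + 15 * np.sin(2 * np.pi * idx.dayofyear / 365.25)
                      + rng.normal(0, 3, len(idx)), index=idx).clip(lower=0)
        beta = h.beta_from_percent(0.24)
        same_day = h.annual_attributable(c, 23.0, beta)
        lagged = h.annual_attributable(c, 23.0, beta, lag_window=4)
        assert lagged == pytest.approx(same_day, rel=0.01)
        const = pd.Series(np.full(100, 50.0),
                          index=pd.date_range("2013-01-01", periods=100))
        assert (h.annual_attributable(const, 10.0, beta, lag_window=4)
                == pytest.approx(h.annual_attributable(const, 10.0, beta)))

    def test_monotone_in_concentration(self):
        idx = pd.date_range("2013-01-01", periods=100)
        base = pd.Series(np.full(100, 40.0), index=idx)
        bumped = base.copy()
        bumped.iloc[13] += 5.0
        beta = h.beta_from_percent(0.24)
        assert (h.annual_attributable(bumped, 10.0, beta)
                > h.annual_attributable(base, 10.0, beta))


def _one_city_scenario(ratio=0.95, aging=True):
    pop10 = pd.Series({"c1": 1_000_000.0})
    f2010 = {"5-64": 0.852, "65-74": 0.052, "75+": 0.030}
    f2050 = ({"5-64": 0.635, "65-74": 0.140, "75+": 0.190} if aging else dict(f2010))
    return PopulationScenario(
        scenario_id="TEST", city_pop_2010=pop10, city_pop_2050=pop10 * ratio,
        age_fraction_2010=f2010, age_fraction_2050=f2050,
        rate_ratio={"5-64": (0.68, 0.35, 1.02), "65-74": (0.50, 0.26, 0.73),
                    "75+": (0.83, 0.61, 1.05)})


def _one_city_baseline():
    rows = [("c1", "cause", "non-accidental", 23.0),
            ("c1", "season", "warm", 21.0),
            ("c1", "age", "5-64", 5.0), ("c1", "age", "65-74", 5.0),
            ("c1", "age", "75+", 13.0)]
    return pd.DataFrame(rows, columns=["city_id", "stratum_type", "stratum",
                                       "mean_daily_deaths"])


class TestFutureBaseline:
    def test_nochange_identity(self):
        base = _one_city_baseline()
        scen = _one_city_scenario(ratio=1.0, aging=False)
        out = h.scale_future_baseline(base, scen, include_aging=False,
                                      include_rate_change=False)
        pd.testing.assert_frame_equal(out, base)

    def test_size_only_scales_all_age_strata(self):
        base = _one_city_baseline()
        scen = _one_city_scenario(ratio=0.95)
        out = h.scale_future_baseline(base, scen, include_aging=False,
                                      include_rate_change=False)
        ages = out[out.stratum_type == "age"]["mean_daily_deaths"].to_numpy()
        want = base[base.stratum_type == "age"]["mean_daily_deaths"].to_numpy() * 0.95
        np.testing.assert_allclose(ages, want)

    def test_cause_and_season_strata_never_rescaled(self):
        base = _one_city_baseline()
        out = h.scale_future_baseline(base, _one_city_scenario(), True, True)
        for stype in ("cause", "season"):
            np.testing.assert_array_equal(
                out[out.stratum_type == stype]["mean_daily_deaths"].to_numpy(),
                base[base.stratum_type == stype]["mean_daily_deaths"].to_numpy())

    def test_full_ladder_matches_hand_computation(self):
        base = _one_city_baseline()
        scen = _one_city_scenario(ratio=0.95)
        out = h.scale_future_baseline(base, scen, True, True)
        # e.g. 75+: 13 × 0.95 × (0.190/0.030) × 0.83
        want = 13.0 * 0.95 * (0.190 / 0.030) * 0.83
        got = out[(out.stratum_type == "age")
                  & (out.stratum == "75+")]["mean_daily_deaths"].iloc[0]
        assert got == pytest.approx(want)

    def test_rate_draw_overrides_central(self):
        base = _one_city_baseline()
        scen = _one_city_scenario(ratio=1.0)
        draw = {"5-64": 1.0, "65-74": 1.0, "75+": 0.5}
        out = h.scale_future_baseline(base, scen, True, True, rate_draw=draw)
        got = out[(out.stratum_type == "age")
                  & (out.stratum == "75+")]["mean_daily_deaths"].iloc[0]
        assert got == pytest.approx(13.0 * (0.190 / 0.030) * 0.5)


class TestExcess:
    def test_trivials(self):
        assert h.excess_mortality(100.0, 100.0) == (0.0, 0.0)
        d, p = h.excess_mortality(110.0, 100.0)
        assert (d, p) == (pytest.approx(10.0), pytest.approx(10.0))

    def test_vector_sums_before_percent(self):
        d, p = h.excess_mortality([60.0, 50.0], [40.0, 60.0])
        assert d == pytest.approx(10.0)
        assert p == pytest.approx(10.0)


class TestStratifiedAssessment:
    @pytest.fixture()
    def fixture_inputs(self, rng):
        idx_h = pd.date_range("2013-01-01", "2013-12-31")
        idx_f = pd.date_range("2053-01-01", "2053-12-31")
        hist = pd.DataFrame({"c1": rng.uniform(20, 80, len(idx_h))}, index=idx_h)
        fut = pd.DataFrame({"c1": rng.uniform(20, 80, len(idx_f))}, index=idx_f)
        crfs = h.default_crf_table()
        return hist, {("rcp85", 1): fut}, crfs, _one_city_baseline()

    def test_zero_exposure_gives_zero(self, fixture_inputs):
        hist, futs, crfs, base = fixture_inputs
        zero_h = hist * 0.0
        zero_f = {k: v * 0.0 for k, v in futs.items()}
        out = h.run_stratified_assessment(zero_h, zero_f, crfs, base,
                                          [_one_city_scenario()])
        assert np.allclose(out["hist_annual"], 0.0)
        assert np.allclose(out["future_annual"], 0.0)

    def test_matches_chained_single_ops(self, fixture_inputs):
        hist, futs, crfs, base = fixture_inputs
        scen = _one_city_scenario(ratio=1.0, aging=False)
        scen = PopulationScenario(
            scenario_id="NOCHANGE", city_pop_2010=scen.city_pop_2010,
            city_pop_2050=scen.city_pop_2050,
            age_fraction_2010=scen.age_fraction_2010,
            age_fraction_2050=scen.age_fraction_2050,
            rate_ratio={a: (1.0, 1.0, 1.0) for a in AGE_GROUPS})
        out = h.run_stratified_assessment(hist, futs, crfs, base, [scen])
        row = out[(out.stratum == "non-accidental")].iloc[0]
        beta = h.beta_from_percent(0.24)
        want_h = h.annualize(h.attributable_daily_deaths(
            23.0, h.attributable_fraction(beta, hist["c1"].to_numpy())))
        want_f = h.annualize(h.attributable_daily_deaths(
            23.0, h.attributable_fraction(beta, futs[("rcp85", 1)]["c1"].to_numpy())))
        assert row.hist_annual == pytest.approx(want_h)
        assert row.future_annual == pytest.approx(want_f)
        assert row.excess == pytest.approx(want_f - want_h)

    def test_season_stratum_uses_only_its_days(self, fixture_inputs):
        hist, futs, crfs, base = fixture_inputs
        # zero out every warm-season day: the warm stratum must vanish
        hist_cold = hist.copy()
        hist_cold.loc[hist_cold.index.month.isin([5, 6, 7, 8, 9, 10]), "c1"] = 0.0
        futs_cold = {k: v.copy() for k, v in futs.items()}
        for v in futs_cold.values():
            v.loc[v.index.month.isin([5, 6, 7, 8, 9, 10]), "c1"] = 0.0
        out = h.run_stratified_assessment(hist_cold, futs_cold, crfs, base,
                                          [_one_city_scenario()])
        warm = out[out.stratum == "warm"].iloc[0]
        assert warm.hist_annual == 0.0
        assert warm.future_annual == 0.0

    def test_stratification_consistency(self, rng):
        """With one shared CRF and identical scaling, the age-summed result
        equals the all-age result exactly."""
        idx = pd.date_range("2013-01-01", "2013-12-31")
        hist = pd.DataFrame({"c1": rng.uniform(20, 80, len(idx))}, index=idx)
        fut = pd.DataFrame({"c1": rng.uniform(20, 80, len(idx))},
                           index=pd.date_range("2053-01-01", "2053-12-31"))
        crfs = pd.DataFrame(
            [("cause", "non-accidental", 0.24, 0.13, 0.35)]
            + [("age", a, 0.24, 0.13, 0.35) for a in AGE_GROUPS],
            columns=["stratum_type", "stratum", "pct", "ci_low", "ci_high"])
        base = pd.DataFrame(
            [("c1", "cause", "non-accidental", 23.0)]
            + [("c1", "age", a, v) for a, v in
               zip(AGE_GROUPS, (5.0, 5.0, 13.0))],
            columns=["city_id", "stratum_type", "stratum", "mean_daily_deaths"])
        scen = _one_city_scenario(ratio=1.0, aging=False)
        out = h.run_stratified_assessment(hist, {("rcp85", 1): fut}, crfs, base,
                                          [scen])
        # NB scenario id "TEST" → treated as aging ladder, but fractions are
        # equal and rates are applied; force rate-neutral comparison instead
        all_age = out[out.stratum == "non-accidental"]
        ages = out[out.stratum_type == "age"]
        assert ages["hist_annual"].sum() == pytest.approx(
            all_age["hist_annual"].iloc[0], rel=1e-12)
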