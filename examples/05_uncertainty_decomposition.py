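"""Monte Carlo intervals and the four-driver decomposition, end to end.

Runs the full experiment on a small configuration and prints the headline
tables: excess deaths with empirical confidence intervals, the seasonal
split, and the incremental decomposition into climate/size/aging/rate
effects.
"""

from ozone_hia.grids import GridSpec
from ozone_hia.pipeline import ExperimentConfig, run_experiment
from ozone_hia.synthetic import TruthConfig

cfg = ExperimentConfig(
    truth=TruthConfig(seed=1, n_sites=14, n_cities=3,
                      coarse_grid=GridSpec(30.0, 110.0, 2.0, 2.5, 2, 2),
                      fine_grid=GridSpec(30.0, 110.0, 0.25, 0.25, 16, 20),
                      historical_period=("2013-05-01", "2014-04-30"),
                      future_period=("2053-05-01", "2054-04-30")),
    n_draws=200, quantile_points=29)
result = run_experiment(cfg)

print("== excess deaths/year, ensemble mean (95% eCI) ==")
s = result.summary
for _, r in s[(s.pop_scenario == "NOCHANGE") & (s.stratum_type == "cause")].iterrows():
    print(f"  {r['rcp']} {r['stratum']:15s} {r['excess_mean']:+8.1f} "
          f"({r['eci_low']:+.1f}, {r['eci_high']:+.1f})  [{r['pct_change']:+.1f}%]")
# negative under the moderate scenario (precursor emissions fall), positive
# under the high scenario (cold-season ozone rises)

print("\n== seasonal split (deaths/year; net row in %) ==")
for _, r in result.seasonal.iterrows():
    print(f"  {r['rcp']} {r['season']:4s} excess {r['excess_mean']:+8.1f} "
          f"pct {r['pct_change']:+6.1f} eCI ({r['eci_low']:+.1f}, {r['eci_high']:+.1f})")

print("\n== driver decomposition (deaths/year), rcp85 ==")
d = result.decomposition
for _, r in d[d.rcp == "rcp85"].iterrows():
    print(f"  {r.pop_scenario}: climate {r.climate_effect:+7.1f}  "
          f"size {r.size_effect:+6.1f}  aging {r.aging_effect:+7.1f}  "
          f"rate {r.rate_effect:+7.1f}  total {r.total:+8.1f}")
# the four effects telescope exactly to the total; aging amplifies the
# burden several-fold while falling death rates partially offset it
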