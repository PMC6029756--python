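"""From hourly concentrations to the MDA8 metric and city exposure series.

Shows the daily-metric rules (75% completeness, 8-hour windows) on simple
hand-built days, then grids a synthetic monitor network and aggregates it
to city level with area weights.
"""

import numpy as np

from ozone_hia import metrics as m
from ozone_hia.synthetic import (TruthConfig, generate_cities,
                                 generate_city_geometry_weights,
                                 generate_site_hourly_obs, generate_sites)
from ozone_hia.grids import GridSpec

# --- the MDA8 metric on single days
print("constant 42 ppb day  ->", m.mda8_from_hourly([42.0] * 24), "ppb")
ramp = list(range(24))
print("ramp 0..23 ppb day   ->", m.mda8_from_hourly(ramp),
      "ppb (mean of hours 16-23)")
sparse = [50.0] * 17 + [np.nan] * 7
print("17 of 24 hours valid ->", m.mda8_from_hourly(sparse),
      "(below the 75% completeness rule -> missing)")
print("100 ug/m3            ->", m.convert_ugm3_to_ppb(100.0),
      "ppb (WHO guideline equivalence)")

# --- a small network, gridded and aggregated to cities
cfg = TruthConfig(seed=7, n_sites=10, n_cities=2,
                  coarse_grid=GridSpec(30.0, 110.0, 2.0, 2.5, 2, 2),
                  fine_grid=GridSpec(30.0, 110.0, 0.25, 0.25, 16, 20),
                  historical_period=("2013-06-01", "2013-08-31"),
                  future_period=("2053-06-01", "2053-08-31"))
cities = generate_cities(cfg)
sites = generate_sites(cfg, cities)
daily = m.site_daily_mda8(generate_site_hourly_obs(cfg, sites))
field = m.grid_site_daily(daily, cfg.fine_grid, times=cfg.dates("historical"))
weights = generate_city_geometry_weights(cfg, cities)
exposure = m.city_series_from_grid(field, weights)

for city in exposure.columns:
    s = exposure[city]
    print(f"{city}: summer mean {m.period_mean(s):.1f} ppb, "
          f"{m.exceedance_fraction(s):.0%} of days above 50 ppb, "
          f"{s.isna().mean():.0%} city-days missing")
# each city-day is the area-weighted mean of the fine cells inside the
# city boundary, renormalized over cells that reported that day
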