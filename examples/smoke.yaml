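# Minimal configuration for a fast end-to-end smoke run:
#   ozone-hia run --config examples/smoke.yaml --out scratch/smoke
truth:
  seed: 9
  n_sites: 8
  n_cities: 2
  coarse_grid: {lat0: 30.0, lon0: 110.0, dlat: 2.0, dlon: 2.5, nlat: 2, nlon: 2}
  fine_grid: {lat0: 30.0, lon0: 110.0, dlat: 0.25, dlon: 0.25, nlat: 16, nlon: 20}
  historical_period: ["2013-05-01", "2014-04-30"]
  future_period: ["2053-05-01", "2054-04-30"]
  n_ensemble: 1
experiment:
  n_draws: 50
  quantile_points: 29
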