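# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a model-description appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Exposure metric

MDA8 is the maximum over the 17 within-day 8-hour windows (start hours
0–16; windows never cross midnight) of the mean of available hours. A
window contributes only with ≥ 6 of 8 valid hours; a day is valid only with
≥ 18 of 24 valid hours (the 75% completeness rule applied to hourly slots).
Missing days are excluded everywhere, never imputed. MDA8 of a complete day
is bounded below by the 24-h mean, which the property suite checks.

Unit conversion is fixed at 2.0 μg/m³ per ppb for ozone (so the 100 μg/m³
air-quality guideline is 50 ppb and the CRF's 10 μg/m³ increment is 5 ppb).
This is the standard-reporting-conditions convention; it is a constant of
the package, not configurable, so that printed equivalences are exact.

## Bias-correction spatial disaggregation (BCSD)

*Quantile mapping.* For each coarse cell and calendar month, daily values
are pooled across all years of the historical period — monthly rather than
day-by-day matching, since a free-running climate model has no day-level
correspondence with reality. Empirical quantiles at K = 99 probability
points q_k = k/(K+1) (linear interpolation; K configurable) give
Q_M and Q_O; the additive bias is b(q) = Q_M(q) − Q_O(q). A daily value x
is assigned its CDF position q* on the *historical model* pool of its
cell-month — also for future values, which operationalizes the assumption
that historical monthly biases persist — and corrected to x − b(q*), with
b interpolated linearly in q and held constant beyond [q_1, q_K].
Correction is monotone non-decreasing in x because both quantile functions
are non-decreasing. Cell-months with an empty model or observation pool are
unusable and propagate missingness rather than being gap-filled; pools
smaller than K/2 trigger a warning.

*Disaggregation.* Daily scaling factors S = corrected − coarse observed
monthly climatology are interpolated to fine cell centers bilinearly
(constant extrapolation beyond the outermost coarse centers) and the fine
observed monthly climatology is added back. Additive (not multiplicative)
anomalies are used throughout, matching the subtract/add construction of
the scaling factors. Climatologies are nearest-neighbor filled (grid-index
metric) with the fill fraction recorded; this is the only gap-filling in
the chain. Concentrations are clamped at 0 ppb after each stage, as
negative mixing ratios are unphysical.

Two identities anchor the correctness of the chain and are enforced by
tests: when model ≡ observations the chain is the identity up to
interpolation tolerance, and correcting the historical model by its own
maps reproduces the observed quantiles at the K probability points (exactly
at the quantile knots; within empirical-quantile spacing distributionally,
with the two outermost points additionally limited by the constant-tail
extrapolation beyond the pooled data range).

## City exposure

City-level daily exposure is Σ w_i · x_i over the fine cells intersecting
the city boundary, with w_i the plane lat–lon area fraction of the overlap
(the minimal reading of a "weighted mean" over member cells; the weight
table is an explicit input, so population or other weights can be
substituted). Weights are renormalized each day over the cells that report;
a day with no reporting member cell is missing. Historical exposure comes
from the gridded observations themselves; future exposure from the
downscaled fields. A station-average mode is not provided; the gridded
route is the one the downscaling chain needs anyway, and the synthetic
generator guarantees at least one monitor per city so the historical series
are populated.

## Health impact assessment

β = ln(1 + pct/100)/5 per ppb, on the log (GLM link) scale from which the
CRFs originate; the difference from the linear-proportion reading is
< 0.01% at these magnitudes. AF = 1 − exp(−β·C) with no threshold, so any
positive concentration contributes. ADD multiplies AF by baseline daily
deaths (Y_b × POP). Daily exposure enters as the same-day city MDA8 by
default; a trailing moving-average window (e.g. 4 days, matching the
lag-0–3 window of the source CRFs) is available as a flag and leaves annual
sums essentially unchanged for smooth series, which is why same-day is the
default.

Annualization: annual deaths = (Σ ADD over covered days) / (covered days /
365.25). Both periods span 918 days (≈ 2.514 years) by construction, so
"annual" totals are comparable across periods and robust to missing days
(a series with half its days missing and constant ADD elsewhere annualizes
to the same value). This period-annualized convention is the only coherent
one for a study window that is not a whole number of calendar years; it is
recorded in the run manifest.

Future baselines: age-stratum baselines scale by the age-group population
ratio (pop₂₀₅₀ f₂₀₅₀,ₐ)/(pop₂₀₁₀ f₂₀₁₀,ₐ) times the age-specific
mortality-rate ratio; with aging disabled they scale by the total-size
ratio only. Cause- and season-stratum baselines are held constant into the
future, since no cause- or season-resolved projections exist — a
conservative convention that confines demographic effects to the
age-stratified results.

## Monte Carlo uncertainty

Coefficient draws are normal on the reported percent scale (where the
normality assumption attaches) with sd = (ci_high − ci_low)/(2 × 1.959964),
then transformed to β. One draw per stratum per iteration is shared across
cities and ensemble members, so totals within a draw are coherent. Negative
CRF draws (possible for respiratory and the youngest age group, whose CIs
cross zero) are retained; negative rate-ratio draws are truncated at zero
(negative death rates are meaningless) and counted. Empirical confidence
intervals take the 2.5th/97.5th percentiles (linear interpolation between
order statistics) of the pooled draws × members distribution — 3,000 values
at the default 1,000 × 3. Pooling, rather than averaging members within a
draw, is the default; the member-resolved outcome arrays are available for
the alternative. Population-projection uncertainty is deliberately
excluded: the scenarios are alternative futures, not a sampled
distribution.

A coverage experiment (1,000 replicated estimations against a known-truth
burden) verifies that the 95% intervals cover at ≈ 95%, which holds because
the draw distribution is centered on an estimate that is itself normal
about the truth with the same sd.

## Driver decomposition

Four nested assessment configurations — no population change; + size;
+ aging; + rate change — all with age-specific CRFs and baselines, give
incremental effects (climate = E0, size = E1−E0, aging = E2−E1, rate =
E3−E2) that telescope exactly to the total change E3. Percent contributions
are relative to the historical age-stratified annual attributable deaths.
The decomposition is computed at point CRFs and central rate ratios on
ensemble-mean excesses.

## Synthetic study conditions

The generator's defaults *are* the study conditions; they are not tuning
knobs. Periods: 2013-04-27..2015-10-31 and 2053-04-27..2055-10-31 (918 days
each). Model bias: constant +17 ppb (a value-dependent variant exists for
stress-testing the quantile mapping). Missingness: 10.6% of site-days
removed whole, plus 1% of individual hours so the completeness rules are
exercised. Three ensemble members differing only in their noise streams
(perturbed-initial-condition analogue). Future seasonal ozone deltas:
moderate scenario warm −16.6 / cold −1.7 ppb; high scenario warm −4.2 /
cold +15.1 ppb.

The latent truth is a smooth separable function of latitude, longitude and
day-of-year plus an AR(1) regional daily weather term (sd 5 ppb, lag-1
correlation 0.6) — enough quantile structure to make monthly bias maps
non-trivial, while keeping daily anomalies spatially uniform so that
perfect-model identity is testable. Site observations add a per-site offset
(sd 1 ppb) and day noise (sd 2 ppb); hourly values follow a fixed diurnal
profile scaled so a complete day's MDA8 recovers the daily target exactly.
The default domain is a 3 × 3 coarse-cell region (6° × 7.5°) with 10 cities
and 40 monitors — every coarse cell and every city is guaranteed a monitor,
mirroring a dense national network. City-level baseline mortality is
lognormal (median 18/day) with fixed stratum shares chosen so age groups
sum to the all-cause mean and the oldest:youngest ratio is 2.6; the
demographic ladder moves the 65+ share from ~8% (2010) to 24–33% (2050)
with total-size ratios 0.944–0.995 and rate ratios 0.68/0.50/0.83 with
their 95% PIs.

What the synthetic data does *not* emulate: realistic atmospheric
chemistry or emission fields, spatially varying demographic trends,
monitor siting bias, instrument drift, or spatially correlated daily
weather beyond the uniform regional term. Passing tests therefore
demonstrate that the *method* recovers known signals under controlled
conditions — bias removal to < 0.5 ppb, trend-sign recovery, interval
coverage — not that any particular real-world burden number is correct.

## Numerical choices and problem sizes

Deterministic seeding throughout: every artifact draws from a dedicated
`SeedSequence([seed, stream_id])` stream, so regeneration is independent of
call order and the full pipeline is bit-reproducible. Grid fields are
xarray DataArrays (time, lat, lon) at cell centers; NetCDF I/O uses the
scipy backend. Empirical quantiles and percentiles use linear
interpolation. Degenerate inputs fail loudly: reversed date ranges,
negative concentrations, zero covered days, sub-2-sample intervals and
non-nesting grids all raise.

The shipped experiment sizes — a 3 × 3 coarse / 24 × 30 fine domain, 10
cities, 918-day periods, 1,000 draws — run the full design in a few seconds
on one CPU; the test suite uses 1-year, 2 × 2-cell configurations for most
properties and the full scale for the acceptance-level checks. These sizes
were chosen as the smallest that leave every estimated quantity's sampling
error well below the tolerances being asserted.

## Known limitations

Single emulated climate model (the dominant real-world uncertainty source
is out of scope by design); no temperature–ozone interaction; no long-term
(cohort) ozone mortality; children under 5 excluded (no CRF); area weights ignore
population density within cities.
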