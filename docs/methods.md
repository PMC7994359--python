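# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the test suite does and does not demonstrate.

## Exposure blending model

The blend is a single province-wide random forest regression
(scikit-learn `RandomForestRegressor`, 1,000 trees, 3 of 6 covariates per
split, bootstrap sampling) of observed 24-h mean station PM2.5 on:

| covariate | timing | definition | default handling |
|---|---|---|---|
| `pm25_lag1` | day−1 | nearest monitoring station's 24-h mean (µg/m³) | required |
| `aod` | day−1 | nearest aerosol optical depth retrieval within 50 km (unitless) | median-imputed when absent |
| `frp` | day−1 | mean fire radiative power within 100 km (MW) | 0 when no fire in range |
| `hms` | day−1 | binary smoke-plume presence at the containing cell | required |
| `vi` | day−1 | venting index at the nearest station (1–100) | required |
| `firework` | day0 | daily mean (hours 1–24) of the 48-h numerical smoke forecast (µg/m³) | required |

Targets are truncated at 150 µg/m³ for internal consistency with the
capped historic exposure model, and predictions are capped at the same
value (and floored at 0).  The cap is applied to *outputs*; the day+1
blend averages the day0 prediction with the numerical forecast's
second-day mean *before* capping, treating the cap as a reporting
constraint rather than part of the arithmetic.  Nearest-neighbour lookups
use planar Euclidean distance in km with ties broken toward the lowest
identifier; radius boundaries are inclusive.  Projection of real
(geodetic) geography to the plane is the caller's responsibility.

Model skill is scored out-of-bag: each training row's prediction averages
only the trees that did not sample it.  OOB RMSE is √(Σ(Pᵢ−Oᵢ)²/n); the
pseudo-R² is 1 − MSE_oob / Var(y) with the population variance of the
targets.  Rows never out of bag (essentially impossible at 1,000 trees)
are excluded with a warning.  The AOD imputation median is recorded at
training and reused verbatim at prediction.

## Health-indicator model

A second forest (1,000 trees, 2 of 5 covariates per split) predicts daily
reliever-inhaler dispensation counts per health area from: (1) day0
population-weighted PM2.5, (2) day−1 population-weighted PM2.5, (3) the
trailing 12-week same-weekday mean count, (4) the trailing 4-week
same-weekday mean, (5) the ISO-8601 week of year.  Training keeps every
date above 15 µg/m³ and a seeded uniform 25% sample of the rest (the smoky
minority is never diluted), over all dates strictly before the first
forecast issue — the two history seasons plus the evaluation year's
pre-season months.  Nothing the season's forecasts are verified against
enters training; a dedicated test corrupts all data on/after an issue date
and asserts bit-identical forecasts.

Holiday handling is two-sided.  Holidays never enter a trailing lookback
(pharmacy closures would bias the weekday trend down); the lookback
extends, to at most twice the window, until enough qualifying weeks are
found.  When the *target* date is itself a holiday, the trailing means are
taken over the most recent Sundays instead: pharmacies close on holidays
as they do on Sundays, so recent Sundays are the observable closure-regime
reference.  Without this, the model predicts weekday-scale counts on the
two statutory holidays inside a July–September season and takes two ~3×
misses per area.  A rule-based British Columbia statutory calendar is
built in; any explicit date set may be supplied instead.

At issue time the day0 forecast substitutes the **maximum** blended day0
PM2.5 over the area's populated cells for covariate (1); day+1 substitutes
the day+1 maximum for (1) and the day0 maximum for (2).  The maximum is
deliberately worst-case and sits above the population-weighted values the
model was trained on, which produces a mild systematic overprediction on
smoky days — a documented property of the emulated design, visible in the
synthetic evaluations.  Forecasts are real-valued ensemble means, floored
at 0, rounded to one decimal only in reports.

## Verification

RMSE, Willmott's index of agreement, per-cent-within-20% (boundary
inclusive; a zero observation counts as hit only for a zero forecast),
RMSE per 10,000 residents, and Pearson correlations of each metric against
health-area population.  Day0 and day+1 horizons are reported separately
and pooled (126 pairs per area for a 63-day season).  Population-weighted
aggregates average the per-area metric values; the IOA is *not* pooled
over concatenated series.  PM forecasts are verified against an uncapped
station comparator: the daily mean over an area's stations, each weighted
by the population of the dissemination areas nearest to it (equal
weighting is available as an option; areas without stations are excluded
from PM verification only, with a warning).  If the comparator's
denominator on some day has no reporting stations, that day is dropped.

## Synthetic study conditions

The generator produces a planar desk-scale province designed to carry the
statistical structure the pipeline assumes; every component is a pure
function of (config, seed) with independent named substreams so, e.g.,
geography can be held fixed while weather varies.

* **Geography** — 4 health areas tiling a 100 × 100 km domain on a 5-km
  grid; 150 DAs per area clustered around 2–4 town centres, populations
  uniform on 400–700 (≈82,000 residents per area, matching the smallest
  real BC health area so that daily counts sit at the tens-per-day scale
  of the real system rather than being Poisson-noise-dominated); 3
  monitoring stations per area placed at jittered DA locations.
* **Season** — evaluation window 15 July–15 September (63 days) of the
  last configured year, preceded by two equally smoky training seasons;
  indicator and exposure series extend 182 days before each window so
  trailing features are always fully defined.
* **Smoke** — truth PM2.5 = day-varying background (log-normal around
  4 µg/m³, σ_log 0.25) plus 4 episodes per window, each Gaussian in space
  (decay 35 km), triangular in time (10–21 days), peaking at 60–150 µg/m³.
  These defaults give provincial season means near the low twenties of
  µg/m³, i.e. an extreme season.  Monitor observations are the closed-form
  truth at the station location plus additive Gaussian noise (σ = 1.5
  µg/m³, floored at 0); AOD is proportional to truth with noise and 70%
  availability; FRP points sit at active episode centres; the plume flag
  marks cells above 20 µg/m³; the venting index falls on smoky days.
* **Numerical forecast** — daily mean = truth × bias × exp(ε) rendered as
  a sinusoidal diurnal profile whose 24-h mean is exact.  The bias rises
  to ×2 (configurable) at episode centres while they burn, emulating
  near-fire overestimation.  The log-normal error ε (σ_log 0.3) is drawn
  once per issue and horizon and shared across the grid: dispersion-model
  error is spatially coherent, and independent per-cell error would make
  the maximum-over-cells extraction inflate with grid size — a pure
  sampling artifact no real forecast field exhibits.
* **Dispensations** — count(h, d) ~ Poisson(λ) with λ = base_rate ·
  pop/10⁴ · dow(weekday) · holiday(d) · exp(β·PM).  Defaults: base rate
  4.5 per 10,000 per weekday, day-of-week multipliers
  (1, 1, 1, 1, 0.95, 0.45, 0.30) Monday→Sunday, holiday multiplier 0.35,
  and β = log(1.3)/22 per µg/m³ — calibrated so a season averaging 22
  µg/m³ above background carries ≈30% excess dispensations, the scale of
  the real 2018-vs-2016 contrast.  An optional gamma-mixing knob provides
  negative-binomial overdispersion (off by default).

What the generator does **not** emulate: plume transport and meteorology
(episodes are stationary Gaussians), spatially varying monitor siting
bias, reporting lags or data outages, population susceptibility structure,
and day-of-week patterns in exposure.  Passing tests therefore demonstrate
that the pipeline recovers the relationships it assumes when those
relationships hold exactly; they do not certify skill on real data.

## Numerical and design choices

* Problem sizes in the test suite (4 areas, 20 × 20 grid, 10–20 replicate
  seeds) were chosen as the smallest configurations at which the
  behavioural properties are statistically unambiguous.
* Robustness to forecast miscalibration is assessed as a *persistent*
  ×2 / ×0.5 scaling of the numerical forecast with the system retrained on
  the scaled history — the blend, anchored to yesterday's monitors, learns
  the miscalibration away.  A transient, unlearned scaling partially
  passes through on day+1, whose averaging rule takes the raw second-day
  forecast at half weight by construction.
* The exposure-response recovery check regresses log(counts+1) on PM; at
  the default count scale (λ ≈ 40) the +1 attenuation is ≈2%, well inside
  the 15% acceptance band.
* `pct_within` treats O = 0 as hit only when P = 0 (holiday closures can
  produce zero counts).
* IOA returns 1 when its denominator vanishes (both series one identical
  constant); it is asymmetric in P and O whenever the series means differ.
* Pseudo-R² may be negative for skill-free models; values are reported
  unclipped, with display clipping left to callers.
* Files round-trip bit-exactly: CSV floats are written with `%.17g` and
  parsed with pandas' `round_trip` converter; given a fixed config and
  seed, every pipeline output is byte-identical across reruns.

## Limitations

The blend is trained at monitor locations, which sit where people live;
its skill in remote unmonitored cells is untested (and in the real system
was the main source of apparent overprediction).  The 150 µg/m³ cap, kept
for fidelity with the emulated system, is known to be inadequate in
seasons whose observations exceed it — about 2% of station-days in the
real 2018 season.  Forecast counts depend on a fixed pre-season training
snapshot; retraining daily would be straightforward but is not done here.
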