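# Methods

`heatrisk` implements an event-based probabilistic assessment of heat-wave
mortality risk for a single surveillance area: heat waves are detected and
quantified with a degree-day intensity index, an age-specific
exposure-lag-response model converts intensity into excess mortality, and a
frequency-severity Monte Carlo turns the fitted hazard and vulnerability
into loss metrics (EP curve, AAL, PML). Because the surveillance and
station data this kind of study uses are not publicly deposited, the
package ships a synthetic-data generator with known ground truth; every
statistical claim the test suite makes is made against that truth.

## Heat-wave definitions and HWII

A heat-wave definition is a triple (temperature metric, threshold rule,
minimum duration). The packaged catalogue holds sixteen definitions
spanning daily mean/maximum/minimum temperature, absolute (35 °C, 37 °C)
and percentile (95th–99th) thresholds, and 2–4 day minimum durations —
the combinations repeatedly used in the heat-mortality literature.
Percentile thresholds are resolved as linear-interpolation empirical
quantiles of the chosen metric over the *full reference record supplied by
the caller*; the reference period is an explicit parameter, never an
internal default, because the resolved threshold (and hence the HWII
scale) depends on it.

An event is a maximal run of consecutive days whose metric strictly
exceeds the resolved threshold, lasting at least the minimum duration
("for over N consecutive days" is read as duration ≥ N, the usual
convention; a strict > N reading is available behind a flag, as is ≥
exceedance). The heat wave intensity index is the sum of daily exceedances

    HWII = Σ_{t=1..dur} (Tmetric_t − thr)   [°C·days]

and the daily exposure series HWII_t carries the covering event's *total*
HWII on each of its days and 0 elsewhere. Events are assigned to the
calendar year of their start day, so annual frequencies are unambiguous at
year boundaries. Missing weather values inside a record are a hard error —
a silent gap would corrupt run detection — and imputation is out of scope.

## The DLNM vulnerability model

The daily outcome is the crude mortality rate of one age group,
Yr_t = deaths_t / population (group deaths over *total* resident
population). The exposure-lag-response is modelled with a cross-basis —
the tensor product of a natural cubic spline in HWII (df_var = 2 columns)
and a lag basis over lags 0..3 (df_lag = 3 columns) — entered in an OLS
regression alongside the confounders: daily mean temperature, relative
humidity, a single linear time trend, day-of-week indicators (Monday
reference) and a binary holiday flag. Identity-link Gaussian OLS on rates
is deliberate: it is the form in which this analysis is conventionally
written for rate outcomes, and the synthetic calibration tests probe
exactly that choice against Poisson-count data.

Basis conventions (the literature states only the df; placement is ours
and fixed for reproducibility):

* Natural cubic splines use the truncated-power construction with the
  natural (zero second derivative) constraint; df counts design columns
  with the intercept excluded, so df + 1 knots are used.
* Exposure dimension: boundary knots at the observed HWII min/max,
  interior knots at equally spaced quantiles of the distinct positive
  (event-day) HWII values; if too few distinct event intensities exist for
  quantile placement the knots fall back to equal spacing on the observed
  range. The basis is evaluated *relative to the centering value*, so a
  series constant at the center produces an all-zero matrix.
* Lag dimension: a constant column plus a natural spline of dimension
  df_lag − 1 with knots equally spaced on [0, max_lag]. The constant
  column means a uniform lag profile is representable, and with df_lag = 1
  the cross-basis degenerates to a moving sum of the exposure basis — the
  unconstrained distributed-lag limit. A lag basis of dimension greater
  than max_lag + 1 has more columns than lag points and is reported as
  non-fittable rather than silently reduced.

The first max_lag rows (incomplete lag history) are dropped from every
fit, so all models compared on one dataset see identical observations.
AIC uses the Gaussian profile form n·log(RSS/n) + 2(k+1) with additive
constants dropped — valid for comparisons because n and the outcome are
fixed across the definition catalogue. Definition selection fits one DLNM
per catalogued definition and takes the arg-min AIC; definitions with zero
events or an unfittable design are recorded in the table and excluded;
exact ties resolve in catalogue order, deterministically.

Centering: the curve is re-expressed about the minimum-mortality HWII,
found as the leftmost arg-min of the uncentered cumulative curve on a grid
over the observed positive-HWII range, followed by one re-fit at that
center (re-centering only shifts the curve vertically, so the arg-min is
center-invariant). The reported vulnerability curve is the lag-cumulative
(0..max_lag) excess crude rate with pointwise 95% bands
central ± 1.96·√(wᵀΣw), where Σ = σ²(XᵀX)⁻¹; it passes through zero at the
center exactly. The grid is also re-expressed as area-specific percentiles
of the observed event HWIIs (min → 0th, max → 100th, linear in between).

Open choices resolved: "long-term and seasonal trends" are entered as the
single linear Time term of the printed model; a natural-spline-of-time
option exists behind `time_spline_df` but is off by default because the
source formulation writes one term. Both the HWII axis and the percentile
axis are emitted, since either reference set (surveillance-period or
climate-period events) can be meaningfully used for standardisation.

## Hazard model

Annual event counts over the reference period (zero-count years included —
the period defines the denominator) get the Poisson MLE λ = mean count.
Event intensities get a Gamma fit; the default is maximum likelihood, with
the shape solving log(a) − ψ(a) = log(x̄) − mean(log x) by Newton iteration
from the method-of-moments start (x̄²/s², s²/x̄) and scale = x̄/a, so the
fitted mean is the sample mean exactly. A pure moments fit is available
for comparison. Near-constant samples are returned at the moment-matched
large-shape limit rather than iterated to overflow. Goodness of fit is a
Pearson χ² on equal-probability bins under the fitted model (continuous:
quantile edges, starting from min(15, n/10) bins; discrete: consecutive
integers grouped left-to-right), merged until every expected count is ≥ 5,
with dof = bins − 1 − fitted parameters and pass defined as p > 0.01.
Calibration of this recipe (~99% pass rate on same-model data at α = 0.01)
is verified in the test suite.

## Risk assessment

A simulated year draws N ~ Poisson(λ) events with i.i.d. Gamma intensities.
Each event contributes the vulnerability curve's value at its HWII — once
per event, not per event-day: the hazard model describes events by
frequency and intensity only, so no duration is available to scale by, and
this single-application convention is the package's key modelling choice.
Curve evaluation interpolates linearly on the stored grid and extrapolates
beyond the observed range with the boundary-segment slope (natural splines
are linear there); negative values, which are sampling noise around the
minimum-mortality center, are floored at zero in loss accounting.

Losses are reported as deaths per million persons per year. Lower, central
and upper vulnerability bands are pushed through one common event stream,
so band ordering and cross-group aggregation hold exactly for every seed;
hazard-parameter uncertainty is not propagated. From the n-year loss
sample: EP(x) = #{years with loss > x}/n; AAL is the mean (identically the
integral of the EP step function); PML at return period T is the smallest
simulated loss whose exceedance probability is ≤ 1/T — the lower-limit
convention, i.e. the empirical (1 − 1/T) quantile. Crude (CMR) losses of a
group convert to age-specific (ASMR) losses by dividing by the group's
population share, and the crude total is the share-weighted ASMR sum,
exactly.

Future projection holds the vulnerability curves fixed, re-detects events
on a future weather series with the threshold *held at its historical
resolved value* (so the HWII scale matches the curves), refits the hazard,
and converts with the future age structure (default elder share 0.3153).
Alternatively (λ, shape, scale) can be supplied directly.

## Synthetic data generator

The generator emulates one area's daily surveillance record:

* **Weather.** tmean = annual mean + seasonal cosine peaking mid-July
  (day 196) + AR(1) noise (`noise_sd` is the innovation SD; the stationary
  SD is noise_sd/√(1−φ²)) + injected hot spells. Spells are explicit —
  Poisson count per year, uniform mid-June–August start, geometric
  duration (mean 4 d), fixed +4 °C excess — so the truth calendar is known
  and recovery tests can be exact. tmax/tmin sit a constant ±4.5 °C around
  tmean.
* **Mortality.** deaths_g(t) ~ Poisson(P·share_g·rate_g(t)) with
  rate_g = baseline_g × day-of-week × holiday × (1+trend)^years ×
  (1 + seasonal term) + Σ_l lag_weights[l]·vuln_g(HWII_{t−l}). The
  vulnerability truth per group is linear, quadratic or hockey-stick in
  the daily HWII exposure of a stated truth definition (default: tmax >
  35 °C for ≥ 3 days), distributed over lags 0–3 with weights (0.4, 0.3,
  0.2, 0.1) — linear in lag, hence exactly representable by the default
  lag basis. Counts are Poisson even though the regression is Gaussian on
  rates: counts are the physical data; the Gaussian fit is the analysis
  choice under test.
* **Confounders.** Relative humidity (clipped normal), an air-pollution
  index with a winter peak, a deterministic three-block holiday calendar,
  a mild winter-peaking mortality seasonality (amplitude 0.10, exposed as
  a knob since within-year mortality seasonality is area-specific).

Default scale: population 650,000; age shares (0.85, 0.15); baseline rates
4×10⁻⁶ (0–64) and 1.4×10⁻⁴ (65+) per person-day; truth slopes 5×10⁻⁷ and
1×10⁻⁵ per °C·day. These produce 2–3 daily deaths in the younger group,
~14 in the elders, a handful of heat waves per summer and elder ASMR AALs
of order 10–100 per million — the magnitudes typical of district-level
surveillance in hot-summer metropolitan areas.

What the generator does *not* emulate: spatially correlated multi-area
weather, cause-of-death structure, mortality displacement (harvesting),
population change within the record, or a varying diurnal range. The last
point means percentile definitions on tmin/tmean/tmax select identical day
sets, so some catalogue pairs are exact AIC ties on synthetic data; ties
resolve by catalogue order. Passing tests therefore demonstrate internal
correctness and statistical calibration under these idealised conditions,
not robustness to the full messiness of real surveillance data.

## Study sizes used by the tests and drivers

The packaged demo is 6 surveillance years with a 45-year weather-only
record for the hazard fit (threshold held at its surveillance-period
value) and a 45-year future scenario (+2.5 °C, doubled spell rate, elder
share 0.3153). Monte Carlo risk uses 10,000 years. Calibration studies in
the test suite use: 200 replicate datasets for null-coverage, 20 years for
linear-slope recovery, 25-year records × 50 replicates for
definition-selection consistency (at 6 years the correlated neighbouring
definitions are separated mostly by noise; 25 years gives AIC enough
information for majority recovery), 2,000 years / 5,000 events for hazard
recovery, and 500 replicates for χ² calibration.

## Known limitations

* Gaussian OLS on rates ignores the Poisson mean-variance relation; CIs
  are honest only to the extent the homoscedastic approximation holds at
  these death counts (the null-calibration test quantifies this).
* AIC comparisons across different max_lag values drop different numbers
  of initial rows; the sweep table is strictly comparable within a fixed
  max_lag.
* Per-event loss ignores event duration beyond its contribution to HWII.
* Hazard-fit parameter uncertainty is not propagated into the loss bands,
  which reflect the vulnerability CI envelope only.
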