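# Methods

`pmnet` implements the quality-assurance and analysis chain for a network
of low-cost optical PM2.5 sensors deployed across urban communities with
regulatory monitors at two of the sites: collocation-based correction,
precision and drift quantification, accuracy evaluation under varying
meteorology, pairwise spatial-variability statistics, community group
comparison, and linkage to a gridded emissions inventory. A synthetic
campaign generator supplies ground truth for every stage.

## Data model and completeness rules

One-minute sensor records carry a raw particle count (hundreds of
particles per cubic foot, hppcf) and/or the mass concentration produced by
the factory retrieval

    PM2.5 (ug/m3) = 0.518 + 0.00274 x count (hppcf),

and the two columns are kept interconvertible through that exact relation.
Hours are labelled by interval start, half-open `[t, t+1h)`. An hourly
mean is reported only when at least 75% of minutes (45 of 60) are present.
The hourly rule is the only completeness rule the campaign design fixes;
for daily means we apply the same 75% fraction (at least 18 of 24 valid
hours), a choice surfaced as a parameter rather than inferred intent.
Negative pollutant values are dropped (never clipped) and counted in the
QC log, so means stay unbiased and data losses are visible. Timestamps
are carried as supplied; day boundaries can be shifted to a local standard
time via an explicit timezone argument.

## Humidity thermodynamics

Dew point is computed by inverting a base-10 Magnus saturation law,
`es(T) = 6.11 * 10^(7.5 T / (237.3 + T))` hPa, through

    Td = (237.3 log10(VP) - 186.52) / (8.29 - log10(VP)).

The two conventions are chosen to be mutually consistent: the round trip
`dew_point(vapor_pressure(T, 100%)) = T` closes to better than 0.1 degC
for T in [-10, 40] (the residual comes from 186.52/237.3 = 0.78601 versus
log10 6.11 = 0.78604 and 8.29 versus 7.5 + 0.786). The logarithm base is
a deliberate convention: base e fails the round trip by tens of degrees,
which the test suite demonstrates.

## Collocation calibration

During collocation all sensors sample the same air, so differences are
instrument response. Each sensor is regressed (OLS) on the all-sensor
hourly mean — the sensor under evaluation included in the mean, matching
the construction of the campaign's published precision table; a
leave-one-out option exists. Fits report slope, intercept, Pearson R2,
and an RMSE defined on raw sensor-minus-mean differences (not regression
residuals), so a pure offset shows up in RMSE but not in R2. A fit is
valid with at least 24 overlapping hours (half of the smallest collocation
N in the published table). The correction factor averages the pre- and
post-study slopes and intercepts; when the post-study fit is invalid the
pre-study fit is used alone, flagged `pre_only`. Correction is the
inverse affine map `(raw - intercept)/slope`; because R2 is invariant
under affine maps, corrected and raw sensors have identical R2 against
the mean — asserted to machine precision in the tests.

The across-sensor coefficient of variation is computed per hour as the
sample SD over the mean across reporting sensors, skipping hours with a
zero mean, then averaged; mean and SD of the hourly CVs are reported.
This per-hour convention follows the comparison literature the campaign
cites and is documented as a choice.

Drift between the collocations is summarised by evaluating both period
regressions at 5, 10, 20, 30, 40, 50 ug/m3. Percent change is referenced
to the pre-period *reading* by default — the most literal reading of the
procedure — with the concentration level itself available as an
alternative denominator, because summary fractions ("share of cases under
10%") are sensitive to this choice.

## Accuracy and meteorological regression

A corrected sensor collocated with an hourly beta-attenuation monitor
(BAM) or daily filter sampler gives accuracy. Because the optical sensor
does not dry its inlet, water uptake by hygroscopic particles inflates its
scattering signal at high humidity; the BAM heats its inlet and does not
share the bias. Two diagnostics are implemented: the sensor/reference
ratio stratified by meteorology (fixed dew-point bins around the growth
onset at 4 degC; quartile bins for other variables), and OLS models of
the reference on the sensor plus covariates from {temperature, dew point,
RH, wind speed}, compared by adjusted R2 = 1 - (1-R2)(n-1)/(n-k-1).
The full quadratic specification adds squares and all pairwise cross
terms: k = 1 + 4 + 4 + 6 = 15 predictors. The reference is the response
(a flag transposes the convention); wind direction is excluded; exactly
collinear terms are dropped with a warning. Single-covariate models are
ranked by adjusted-R2 gain; rankings are invariant to affine covariate
rescaling (asserted in tests).

## Spatial statistics

The coefficient of divergence for aligned site series x, y is
`sqrt(mean(((x_i - y_i)/(x_i + y_i))^2))`: 0 for identical series, 1 for
complete divergence, with 0.2 the conventional heterogeneity threshold
(pairs at exactly 0.2 are labelled heterogeneous). Pairs summing to zero
carry no relative information and are skipped with a count; exact zeros
are rare in winter PM after correction. Pairwise matrices (COD and
squared Pearson correlation) are built per site pair on the pairwise
overlap, with minimum-overlap floors of 72 hours / 14 days (configurable);
hourly matrices use corrected hourly values and daily matrices use daily
means built under the daily completeness rule. Distances are great-circle
with Earth radius 6371 km, and distance decay is a simple OLS of the
pairwise statistic on pairwise distance (slope sign reported, not
enforced).

Global Moran's I uses row-standardized weights (inverse distance by
default, k-nearest available) and a permutation p-value, two-sided around
the permutation-null expectation -1/(n-1), with the (1+k)/(n_perm+1)
estimator. The implementation is vectorized and cross-checked against a
literal double-sum oracle to 1e-12; the permutation test rejects at the
nominal rate on i.i.d. values.

Community comparison offers a pooled Welch t-test (EJ versus non-EJ
hourly values) and per-site-pair two-sided rank-sum tests, exact when
sample sizes permit and normal-approximated otherwise, reported raw with
an optional Holm-adjusted column (the campaign convention quotes raw
pairwise p-values). Exact p-values match brute-force enumeration for
group sizes up to six. Note the pooled Welch test treats hours as
independent; with a strong shared regional signal its standard error is
overestimated for the group contrast, making it conservative — the
null-calibration test quantifies this.

## Emissions-inventory linkage

Grid cells are half-open axis-aligned 4 x 4 km squares on a local
equirectangular km projection (adequate at city scale); boundary points
belong to the lower-left cell. For each cell and day type (weekday
Mon-Fri by the local calendar; holidays count as weekdays unless listed),
the cell mean uses only hours when every member sensor reports, and the
increment subtracts the lowest cell mean within that day type — the
"background" cell, of which there is exactly one per day type. The
lowest-cell background is the most literal reading of the procedure; a
fixed-percentile alternative is available. Increments are regressed on
the inventory's tons/day; R2 is invariant to emission units, and residual
ranking flags cells where monitors may be unrepresentative or where
processes the inventory omits (secondary aerosol, transport) dominate.

## The synthetic campaign generator

The generator emulates a ~19-sensor, 15-site, 6-community winter
deployment with a 7-day pre-study collocation, ~2-month deployment, and
~1-month post-study collocation, two sites hosting reference monitors and
three sensors each.

**Truth field.** A shared regional log-normal baseline (median 12 ug/m3,
log-SD 0.45, AR(1) with ~2-day persistence) is modulated by a diurnal
factor rising from 16:00 to an overnight plateau (~1.9x) with an
afternoon minimum (~0.45x) — the wintertime residential-burning/shallow-
boundary-layer pattern. On top sit (a) a *static* spatially correlated
site gradient (log-SD 0.15, exponential correlation over distance,
default length 8 km), giving the persistent few-ug/m3 neighborhood
differences an emissions inventory can mirror; (b) an hourly correlated
site noise field (log-SD 0.12, AR 0.9); and (c) a nocturnal spike process
(correlated positive excursions, amplitude 6 ug/m3, 18:00-03:00). The
static gradient is demeaned within the EJ and non-EJ groups so that the
realized group difference equals the `ej_effect` parameter exactly and
nothing else — group tests are calibrated against a true null by
construction. An infinite correlation length with spikes disabled
degenerates to identical site series.

**Meteorology.** Dew point is AR(1) (mean 6 degC, SD 3 degC, ~2-day
decorrelation), spanning the unbiased (<4 degC) and strong-growth
(>10 degC) regimes within one deployment. Temperature is the dew point
plus a diurnal gap that collapses to <1 degC overnight and whose daytime
amplitude varies day to day (clear versus overcast) independently of
moisture — so roughly 65% of hours sit at RH >= 85%, and temperature is a
noisy rather than perfect proxy for the humidity-bias driver. RH follows
from the two by the same Magnus law the analysis uses.

**Sensors and references.** Each sensor observes its site's truth through
`growth(dp) x (slope x truth + intercept) + noise`, with per-sensor
slopes/intercepts drawn from the ranges the published collocation table
spans ([0.78, 1.64] and [-3.2, 2.6] ug/m3), minute noise SD 1 ug/m3, and
minutes dropped independently at 5%. The growth factor is piecewise
linear in dew point — 1 below 4 degC, slope 0.2/degC, hence 3 at 14 degC,
matching the observed 1x-to-3x bias envelope; a scattering-enhancement
alternative `1 + c*RH/(100-RH)` is available, and tests depend only on
monotonicity. Particle counts are the exact retrieval inverse of the
simulated mass. The hourly BAM multiplies truth by `1 + N(0, 0.11)`
(half of the ~22% two-instrument precision figure); the daily filter
sampler is near-truth (3% noise). A fast path generates hourly
observations directly with noise SD `noise_sd/sqrt(60)`, used by
multi-replicate statistical tests; the minute path is the default.

**Emissions grid.** Occupied 4 x 4 km cells get weekday/weekend emissions
proportional to their long-run truth increment (plus a 0.5 ug/m3 base so
the background cell still emits), distorted by multiplicative log-normal
noise with log-SD 0.5 — chosen once so the increment-versus-inventory R2
typically falls in the 0.4-0.9 band around the mid-0.5s. Zero distortion
makes the regression exact by construction.

**What the generator does not emulate.** No atmospheric chemistry,
transport, or dispersion; no spatial structure in meteorology (one met
series serves the whole domain); no sensor aging or drift within a
deployment (pre/post response is identical apart from refitted noise); no
diurnal structure in dew point; missingness is independent rather than
burst-like. Passing tests therefore show the *statistical machinery* is
correct under the stated data-generating assumptions, not that a real
network will meet the same numbers.

## Numerical and design choices

- Parameter recovery is verified with the growth bias disabled: growth is
  a common-mode multiplicative factor that the affine correction
  deliberately leaves in place, and with it enabled the injected
  (slope, intercept) pair is no longer the ground truth of an affine
  sensor-versus-mean relation. Recovery at 168 collocation hours is
  within ~0.5% (slope) and ~0.06 ug/m3 (intercept), against acceptance
  bands of 2% and 0.3.
- The network-mean quorum is 75% of sensors reporting in an hour;
  fit floor 24 hours; pairwise overlap floors 72 hours / 14 days.
  Simulation problem sizes in the tests: full-scale campaigns at minute
  resolution for aggregation and calibration; hour-resolution campaigns
  and 50-replicate regional fields for distributional properties.
- Ties in the rank-sum test switch scipy to the normal approximation;
  the exactness guarantee (and the enumeration cross-check) applies to
  tie-free data.
- Corrected values can be negative (small raw values under a positive
  intercept); they are retained and logged, not clipped.
- Which sensors fall back to pre-only corrections is decided per sensor
  from post-period fit validity, since the campaign record does not name
  them.
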