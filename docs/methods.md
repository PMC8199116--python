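# Methods

This note documents the models, defaults and numerical choices behind
`lurex`, and what the synthetic-city tests do and do not demonstrate about
real data.

## Land use regression

The concentration model is ordinary least squares on buffered covariates,

    PM2.5(s) = b0 + sum_k bk * mean_{||u - s|| <= r_k} cov_k(u) + e(s),

fit to per-site mean concentrations for one averaging period (a season or
the year). Hour-level regression is deliberately out of scope: LUR is most
defensible for long-period averages, and hourly structure is reintroduced
multiplicatively (below).

**Buffer search.** For every covariate the circular focal mean is computed
at each rung of a radius ladder and extracted at the sites; the rung with
the largest |Pearson r| against the response wins, ties breaking toward
the smaller radius (the more local, more parsimonious neighborhood).
Correlation is computed on untransformed values; the absolute value is
maximized because predictors legitimately carry either sign. The default
ladder spans 30 m steps near zero, 90 m steps to 1.5 km and 300 m steps to
~5 km, and always contains every radius that appears in the published
Beijing prediction functions bundled with the package; an exhaustive 30 m
ladder is available by configuration. Rungs below half a cell are dropped
(the kernel would be empty).

**Focal means.** Kernel membership is by cell-center distance; at the
domain boundary the kernel is truncated rather than padded, which keeps
the statistic an unbiased mean of observed cells. Nodata cells are omitted
from the numerator and denominator; an all-nodata neighborhood yields
nodata. The implementation is FFT convolution of the value and validity
planes; a direct enumeration (`focal_mean_brute`) is kept as the test
oracle.

**Stepwise selection.** Bidirectional: the forward step adds the candidate
with the smallest coefficient t-test p-value if it is below `p_enter`
(0.05); the backward step removes any included term whose p-value exceeds
`p_remove` (0.10). Candidates whose pairwise |r| with an included term
exceeds 0.8 are skipped at entry. Because `p_enter <= p_remove`, a
variable cannot oscillate in and out on fixed data, so the loop terminates
within `2 * n_candidates` iterations (asserted). The selection criterion
(p-of-t, equivalent to partial F for one added term) is a choice; an
information-criterion variant would be a natural extension but is not
implemented.

**Diagnostics.** Model R², adjusted R² (NaN when n <= p+1), MAE and RMSE
on modeling residuals. Leave-one-out CV refits the *coefficients* of the
fixed selected term set on each n−1 subset and predicts the held-out site;
CV R² is 1 − SSE/SST against the observed mean. Selection is not repeated
per fold: CV then measures the chosen model rather than the selector,
matching common LUR practice and keeping CV R² interpretable against
model R². Negative predicted cells are floored at 0 μg/m³ and counted in
the log; diagnostics are computed on unfloored values.

## Diurnal adjustment

Hourly factors for a period are the 24 pooled hourly mean concentrations
divided by their *unweighted* daily mean, then renormalized once so the
factors average to exactly 1 (double precision). Using the mean of hourly
means rather than the mean of raw observations makes the conservation
identity exact regardless of per-hour observation counts: the 24 hourly
maps average cellwise back to the base map to ~1e-15 relative error, and
scaling preserves the spatial rank order within every hour. Observations
are cleaned first: values strictly above 1000 μg/m³ (instrument spikes)
and missing records are dropped, with counts reported by cause; a value
exactly at the threshold is retained.

## Population dynamics

Hourly device counts are standardized column-by-column to the mean of the
24 raw totals. Any constant target would leave every weighted mean
unchanged (weights enter homogeneously); the mean of totals is chosen so
the standardized matrix stays on the scale of the data. Standardization is
idempotent and conserves the reference total at every hour.

The commute table compares the standardized population inside each nested
ring at 15:00 (work) and 02:00 (home), as percent of the total. Entries
are cumulative within nested rings — "inside ring k" — so the outside
zone's entry is exactly the negative of the outermost ring's, and on the
synthetic default (all commuters flowing inward from outside the rings)
the entries increase monotonically outward. Population is treated as
located at the station point; no spatial disaggregation of a station's
catchment is attempted, mirroring the positioning limit of tower-level
data.

## Exposure

City exposure at hour h is `sum_i w_ih c_i / sum_i w_ih` over stations.
In commute-only mode the concentrations come from the one fixed period
map, so all hourly variation is population movement; in combined mode the
hourly maps are used, and because those are uniform rescalings,
`combined[h] = commute_only[h] * factor[h]` holds exactly and is asserted
numerically. Exposure curves are empirical weighted CDFs of station
concentrations, no smoothing; the identity `mean = sum c * pmf` ties them
back to the weighted mean. The five-way comparison reports: one reference
site's observed mean; the mean of all sites; the map mean over valid
cells; the census-weighted map mean (coarse census raster brought onto
the map grid by nearest-neighbor resampling); and the mobile-weighted
value using the 24-hour day-average of the standardized weights (a single
hour can be pinned by configuration — the averaging convention for this
measure is genuinely open, and the day-average is the least arbitrary
default).

## Synthetic city

The generator provides the statistical structure the analysis assumes,
at desk scale, from one config and one seed (per-stage streams are spawned
from a single `SeedSequence`, so stages are individually reproducible).

* **Domain.** 90 × 90 km at 450 m cells (200 × 200). The domain is kept
  near real municipal scale because the regional gradient term is printed
  in μg/m³ *per km* of DTS: on a toy-sized domain that term would span
  only a few μg/m³ and be statistically unrecoverable against realistic
  site noise. Cell size is configurable (e.g. 30–90 m on small domains).
* **Covariates.** DTS is the exact planar distance of each cell center to
  the south edge (km), deterministic, constant along rows and increasing
  northward. Slope, NDVI, AOD and road density are smoothed Gaussian
  fields (configurable correlation length, 4.5 km default; terrain uses
  twice that, since real topography varies on longer scales) with mild
  north/south trends: more slope and vegetation in the mountainous north,
  more aerosol in the south, road density peaking at the urban core. The
  trends are kept mild so covariates stay statistically separable from
  DTS — a city where terrain is collinear with latitude cannot identify
  both coefficients, with 35 sites, no matter the method.
* **Truth and observations.** The true surface is linear in buffered
  covariates (default mirrors the published yearly function: 115.83 −
  0.48·DTS@2400 − 1.15·Slope@4620, floored at 0), with seasonal intercept
  levels (0.92/0.77/0.98/1.34 of yearly — winter haze highest, summer
  lowest). Site observations are seasonal truth × that season's diurnal
  multiplier + N(0, 4.33) μg/m³ (the published yearly modeling RMSE), with
  0.1% gross outliers drawn above 1000 μg/m³ and 5% of records deleted.
  Sites are drawn with probability ∝ 0.5 + road density: a monitoring
  network prefers busy areas but is designed for whole-domain coverage.
  Default diurnal multipliers are two-harmonic cosine profiles (exact unit
  mean) with night maxima in autumn/winter and a distinct morning-rush
  bump in summer.
* **Population.** 400 stations (half clustered around the core, half
  uniform), 20,000 agents. Homes are uniform across stations; commuters
  (15% of agents, drawn from homes beyond the outermost ring) work at
  core-weighted stations, are home 19:00–07:00, at work 09:00–17:00, and
  in transit (nearest station to the home–work midpoint) otherwise.
  Devices connect per hour with probability 0.28–0.95 (night to day), so
  raw totals swing ~3.4-fold — the artifact standardization must remove.
  Nearest-station allocation stands in for strongest-signal allocation:
  equivalent under equal-power stations, and deterministic.
* **Rings.** Concentric circles (2nd…5th, 4–13 km) around the urban core,
  which sits south of the domain centroid so that work zones occupy the
  higher-PM2.5 side of the gradient.

**What passing tests show, and what they do not.** The synthetic city has
Gaussian noise, linear truth, isotropic covariate fields, a single
monocentric commute pattern and no weekday/weekend or meteorological
structure. Tests against it validate the *computational chain* — buffer
search, selection, conservation identities, weighting — and the
statistical calibration of that chain under the stated noise model. They
do not validate LUR as a physical model of any real city's PM2.5, the
phone-to-person ratio's stability over space and time, or positioning
error at the station level.

## Problem sizes and numerical tolerances

Default test and validation sizes: 200 × 200 grid, 35 sites, 400 stations,
20,000 agents, 10 days per season of hourly observations; the parameter
recovery experiment uses 100 seeds of the 35-site simulation with site
noise applied directly to the per-site period mean. Conservation
identities are asserted at 1e-9 relative error or tighter; focal-mean
FFT results agree with direct enumeration to better than 1e-8 relative;
coefficient recovery in the noise-free limit is exact to 1e-6 relative.
Degenerate inputs fail loudly: zero-variance covariates, empty hours,
zero-total hours, zero weight sums and out-of-extent points all raise
errors naming the offender, while an empty stepwise selection returns an
intercept-only model with a warning.

## Known limitations

Exposure is outdoor-only, at station points, with no vertical (building
height), indoor-infiltration or dose component; factors are spatially
uniform within an hour; the census stand-in is derived from the same agent
homes as the mobile weights, so the census-vs-mobile gap on synthetic data
is smaller than a real census would produce; and the real study's numeric
headline values depend on proprietary operator counts and municipal GIS
stacks that are not redistributable, so they are not reproduced here —
the worked-example evaluations of the published prediction functions are.
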