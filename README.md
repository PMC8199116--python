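# lurex

Dynamic population-weighted PM2.5 exposure assessment: land use regression
(LUR) concentration surfaces, diurnal scaling to hourly maps, hourly
population distributions from cell-tower device counts, and the exposure
statistics that combine them.

## The problem

City-level exposure assessment usually pairs a static population (census,
home addresses) with sparse monitor averages. Both halves are wrong in an
interesting way: pollution varies block by block, and people spend their
days somewhere other than home. `lurex` implements the dynamic alternative
for a monocentric megacity:

1. **LUR surface.** Observed mean PM2.5 at ~35 monitoring sites is
   regressed on geographic covariates — distance to the south boundary
   (DTS, km), terrain slope (%), NDVI, aerosol optical depth (AOD) and
   road density — each averaged over a circular buffer. The buffer radius
   per covariate is chosen by a *distance-decay search*: scan a ladder of
   radii, keep the radius with the largest |Pearson r| against PM2.5.
   Predictors then enter a bidirectional stepwise OLS
   (p-enter 0.05, p-remove 0.10, pairwise |r| ≤ 0.8 collinearity gate):

   `PM2.5 = b0 + Σk bk · cov_k@radius_k`

   Diagnostics: model/adjusted R², leave-one-out CV R², MAE, RMSE.
2. **Hourly maps.** The 24-hour mean concentration cycle of the cleaned
   observations (outliers > 1000 μg/m³ dropped), divided by its daily mean,
   gives hourly adjustment factors with mean exactly 1; each factor scales
   the seasonal or yearly map, so the hourly maps average back to the base
   map by construction.
3. **Hourly population.** Base-station device counts swing several-fold
   between night and day (phones go idle), so each hourly column is
   standardized to a common total before use; spatial shares are untouched.
   Comparing the in-ring population at 15:00 vs 02:00 quantifies the net
   commute into each nested ring road.
4. **Exposure.** Station-level concentrations weighted by the hourly
   population give the city-level exposure series, decomposed into a
   commute-only part (fixed map) and a combined part (hourly maps), plus
   weighted cumulative exposure curves and a five-way comparison of
   exposure measures (single reference site, mean of sites, map mean,
   census-weighted, mobile-population-weighted).

Because operator phone counts and municipal covariate stacks are not
redistributable, the package ships a first-class **synthetic city
generator** (`lurex.synthetic`): autocorrelated covariate rasters with a
south-to-north pollution gradient, a linear ground-truth surface, noisy
seasonal site observations with rare gross outliers, urban-dense base
stations, and a home/work commute model. Every stage of the analysis is
tested against it.

## Worked example

Evaluate a bundled published yearly prediction function
(`115.83 − 0.48·DTS2400m − 1.15·Slope4620m`) and run the full synthetic
pipeline:

```python
import lurex
from lurex.pipeline import RunConfig, run_stages

models = {m.season: m for m in lurex.load_printed_models()}
lurex.evaluate_model(models["yearly"], {"DTS": 10.0, "Slope": 5.0})
# 105.28   (115.83 - 0.48*10 - 1.15*5, in ug/m3)

res = run_stages(RunConfig(seed=1))
```

The seed-1 run prints, via the objects in `res`:

```text
fitted yearly model: 116.27 -0.483*DTS5010m -1.151*Slope5010m
adj R2 = 1.000, CV R2 = 1.000, RMSE = 0.27
commute (% of population): {'2nd': 4.2, '3rd': 7.5, '4th': 11.7, '5th': 14.0, 'outside': -14.0}
exposure at 02:00 / 15:00 (commute only): 86.81 / 87.09 ug/m3
measures: site 86.2 | sites-mean 77.7 | map 82.5 | census 86.9 | mobile 87.0
```

Reading this: the stepwise chain recovered the generator's truth
(intercept 115.83, DTS −0.48, Slope −1.15) almost exactly; 14% of the
synthetic population commutes into the 5th ring by day (cumulative and
monotone across rings, with the outside zone the exact negative);
commuting alone raises city exposure at 15:00 over 02:00 because work
zones sit in the higher-PM core; and the mobile-population-weighted
measure exceeds the census-weighted one for the same reason.

The same pipeline is available from the shell:

```sh
lurex all --seed 1 --outdir run1        # writes rasters, CSVs, manifest
lurex printed-models                    # show the bundled models
```

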