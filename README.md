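# stcoverage

**Spatio-temporal semivariogram modelling and coverage analysis for
air-quality monitoring networks.**

How far away from a monitoring station — in kilometres and in weeks — are
pollutant measurements still informative?  `stcoverage` answers this for a
network of fixed stations reporting hourly concentrations (the motivating
case is a metropolitan network such as Mexico City's RAMA/SIMAT): it
estimates the spatial and temporal correlation ranges of each pollutant from
the data alone, without interpolating concentrations, and turns the spatial
range into per-year *representativeness maps* — the union of circles of that
radius around the stations active each year.

## Method

1. **Weekly aggregation.** Hourly series are averaged to ISO weeks; a
   station-week is kept only if more than 5 days contain at least 17 hourly
   records each.  A station × week completeness grid documents gaps
   (late activations, outages, shutdowns).
2. **Empirical space-time semivariogram.** For spatial-distance bin h and
   weekly lag u,

   γ̂(h, u) = 1/(2 N(h,u)) Σ [Z(sᵢ, t) − Z(sⱼ, t+u)]²,

   over all unordered observation pairs with great-circle separation in bin
   h and time separation u; N(h, u) pairs per cell.
3. **Structure fitting.** Five space-time covariance structures —
   *separable*, *productSum*, *metric*, *sumMetric*, *simpleSumMetric* —
   are composed from exponential / spherical / Gaussian components
   (nugget n, sill s, range r, practical-range constant a = 1/3, so the
   asymptotic families reach 95% of the sill at h = r).  Every structure ×
   family assignment (75 candidates) is fitted by weighted least squares
   from data-derived initial values and the minimum weighted-MSE candidate
   wins.
4. **Coverage maps.** The winner's spatial range is the radius of a circle
   around every active station; the union of circles, intersected with the
   study-region polygon, gives the covered area and region fraction per
   year.

A synthetic-data module simulates station networks and Gaussian random
fields with known space-time semivariograms (plus realistic missingness),
so the whole pipeline is testable end-to-end and parameter recovery can be
quantified.

## Worked example

```python
import stcoverage as sc

truth = sc.SpaceTimeVariogram(
    "separable",
    spatial=sc.ComponentVariogram("exponential", 0.1, 1.0, 40.0),   # 40 km
    temporal=sc.ComponentVariogram("exponential", 0.1, 1.0, 8.0),   # 8 weeks
    sill=1.0,
)
catalogue = sc.generate_network(n_stations=30,
                                region=(-99.35, 19.15, -98.78, 19.70), seed=1)
panel = sc.simulate_field(catalogue, 200, truth, seed=2)
emp = sc.empirical_st_variogram(panel, catalogue, max_temporal_lag=20)
res = sc.SpaceTimeVariogramModel(
    emp, "separable", ("exponential", "exponential")).fit()
print(res.summary())
```

```
Space-time variogram fit
========================================
candidate        separable:exponential+exponential
n cells          335
WMSE             0.00137982
converged        True
spatial range    34.41 km
temporal range   7.01 weeks
----------------------------------------
sill                   0.989733
spatial_rel_nugget     0.049937
spatial_range          34.4089
temporal_rel_nugget    0.0594683
temporal_range         7.01014
```

The fitted spatial range (34.4 km) and temporal range (7.0 weeks) recover
the simulation truth (40 km, 8 weeks) from a single realisation; across 20
replicates the spatial range lands within ±25% of truth in ≥ 80% of runs.
`grid_search(emp)` fits all 75 candidates and returns the winner plus a
leaderboard; `coverage_timeline(panel, catalogue, res.spatial_range_km,
region, years)` then yields one union-of-circles map per year.

The same pipeline runs from the shell on CSV/GeoJSON inputs:

```sh
stcoverage simulate --n-stations 20 --n-weeks 104 --outdir data/
stcoverage run --config config.yaml --outdir out/ --seed 1
```

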