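# climate-analogs

Climate-analog mapping for cities: given the climate a city is expected to
have decades from now, find the place whose *present-day* climate matches it
best — "by the 2080s, city X will feel like today's city Y" — and quantify
how good (or how impossible) that match is.

The package implements the sigma-dissimilarity analog pipeline end to end:
seasonal climate grids, station-based interannual variability, the statistic
itself, best-analog search with geodesic distance and bearing, analog-class
thresholds, multi-model ensembles, cohort summaries, and machine-readable
layer export — plus a synthetic-data module that generates every input with
known structure so the whole chain is testable offline.

## The statistic

Climate at one place/time is a 12-vector **x** = (tmin, tmax, prcp for DJF,
MAM, JJA, SON; °C and mm). For a city with future climate **x** and a
candidate grid cell with contemporary climate **y**,

- **Mahalanobis distance** D = √((x−y)ᵀ Σ⁻¹ (x−y)), where Σ is the city's
  **interannual climatic variability (ICV)**: the 12×12 year-to-year
  covariance of its seasonal climate estimated from 1960–1990 monthly
  station records (5-station / 50-km selection rule, inverse-distance
  weighting toward the centroid, DJF lagging December). Scaling by ICV makes
  D unitless and scale-invariant: differences are measured against the
  fluctuations residents already experience.
- For **x** drawn from the ICV distribution around **y**, D follows a chi
  distribution with n degrees of freedom (n = retained climate dimensions,
  12 by default), so p = P(χₙ ≤ D) is D's percentile.
- **Sigma dissimilarity** σ = chi-quantile(p; 1 dof) re-expresses that
  percentile as a z-score-like value on a common scale: 2σ is the 95th
  percentile, 4σ the 99.994th. σ ≤ 2 → **representative** analog;
  2 < σ ≤ 4 → poor; σ > 4 → **novel** climate (no modern equivalent in the
  search domain).

Ensembles are averaged on climate variables *before* the statistic — a mean
of sigma surfaces is never computed. Extreme percentiles are handled in log
space (log survival function) and saturate, flagged, at a 12σ cap.

## Worked example

```python
import numpy as np
from climate_analogs import ICVModel, best_analog, similarity_surface
from climate_analogs.synthetic import (
    SyntheticConfig, make_grid, make_urban_polygon, plant_future)

grid = make_grid(SyntheticConfig(seed=42))            # contemporary pool
icv_sd = np.array([1.0]*8 + [40.0]*4)                 # °C / mm interannual sd
icv = ICVModel(mean=np.zeros(12), covariance=np.diag(icv_sd**2), retained_dims=12)
city = make_urban_polygon((40.0, -95.0), 150.0, name="Demo City")

future = plant_future(grid, (22, 25))                 # future = known cell's climate
res = best_analog(similarity_surface(future, grid, icv), city)
print(res.best_lat, res.best_lon, res.min_sigma, res.analog_class)
```

prints `50.0 -85.375 0.0 representative`: the search recovers the planted
cell exactly, at 0σ (a perfect analog). Adding +2 °C to every seasonal
temperature moves the best analog to latitude 46.0 — equatorward, as a
warmer future must on a grid where temperature falls with latitude (see
`examples/02_planted_analog.py`; the other `examples/` scripts walk through
the sigma scale, ICV estimation, ensemble scenario runs, and layer export).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds a complete synthetic world from the seed — analog pool, cities,
station records, estimated ICV per city, two emission trajectories with
five members each — runs the urban-area filters and the ensemble-mean
pipeline, and prints the per-city analog table, per-member results, and
cohort summaries (mean analog distance and bearing, representative/novel
fractions per trajectory), writing its JSON report to `--out`.

The headline numbers of the original continental-scale analysis (mean analog
distances of hundreds of km, novelty fractions per emission trajectory)
require the real gridded normals, 27-model downscaled projections, station
archives, and urban-area shapefiles, which are external downloads; they are
out of scope here. The synthetic world reproduces the qualitative behaviour
(southward analogs, roughly doubled distances under unmitigated emissions)
and every quantitative property of the method itself.
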