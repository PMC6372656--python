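# Methods

## Model

Climate state is the 12-vector of seasonal minimum temperature, maximum
temperature (°C, 3-month means) and total precipitation (mm, 3-month sums)
over the climatological seasons DJF, MAM, JJA, SON. Analog quality between a
city's future climate x and a contemporary grid-cell climate y is measured
in three steps:

1. **ICV-standardized Mahalanobis distance.** D = √((x−y)ᵀ Σ⁻¹ (x−y)),
   with Σ the city's interannual covariance (below). D is invariant to
   rescaling any variable (units cancel) and discounts directions in which
   variables co-fluctuate, so correlated variables are not double-counted.
   Computed by Cholesky factorization and triangular solves, never an
   explicit inverse; a non-positive-definite Σ raises an error naming the
   most collinear variable pair, with an optional ridge jitter (off by
   default).
2. **Chi percentile.** If x varied around y only by interannual noise,
   D ~ chi(n) with n the number of retained climate dimensions. p =
   P(chi(n) ≤ D) is the percentile of the observed distance within that
   null. The log survival function is carried alongside p, computed in log
   space (with an asymptotic upper-incomplete-gamma expansion once the
   survival probability underflows), so extreme distances remain ordered
   after p rounds to 1.
3. **Sigma scale.** σ = chi-quantile(p; 1), putting every city on a common
   z-score-like scale regardless of n. Anchors: σ=2 ↔ 95th percentile,
   σ=4 ↔ 99.994th. Inversion uses two branches: below the median,
   σ = √2·erfinv(p) with p = −expm1(log sf), accurate down to σ ≈ 1e−300
   (near-perfect analogs never collapse to exactly 0σ and argmin ties stay
   meaningful); above it, σ = −ndtri_exp(log sf − log 2), accurate long
   after p saturates in double precision. Beyond a cap (default 12σ) the
   value is the cap with `saturated=True` — past that point the exact
   number carries no information. At n = 1 the percentile/quantile round
   trip is the identity, so the implementation shortcuts σ = min(D, cap)
   to make the dof-1 identity exact.

Classification: σ ≤ 2 representative, 2 < σ ≤ 4 poor, σ > 4 novel. The
boundaries sit on the representative/poor side (2σ is still representative,
4σ still poor).

## ICV estimation

Monthly station records (tmin, tmax, prcp) over a reference window
(default 1960–1990) feed the estimate:

- **Selection.** All complete in-polygon stations if ≥ 5; otherwise the
  nearest complete stations within 50 km of the centroid top up to 5.
  "Complete" = no missing month for any variable in the window. Ordering is
  (distance, station id), so results are independent of input order. Cities
  that cannot satisfy the rule are excluded, not patched.
- **Combination.** Inverse-distance weighting toward the centroid, weight
  1/d^p with p = 1 by default (exposed in the API); distances floored at
  1 m so a station on the centroid stays finite.
- **Seasonal aggregation.** Temperature = 3-month mean, precipitation =
  3-month sum; DJF of year Y uses December of Y−1 (standard climatological
  convention), so a 31-year monthly window yields 30 complete seasonal
  years.
- **Covariance.** Sample covariance (divisor n−1) of the annual 12-vectors.
  Optional per-variable linear detrending (off by default: with a 30-year
  window the secular trend is small relative to interannual noise, and the
  plain covariance is the more conservative, larger estimate). Optional PCA
  truncation by a standard-deviation threshold re-expresses Σ on its
  principal axes and sets n to the retained count (minimum 1; numerically
  null eigenvalues are excluded regardless of threshold); default is no
  truncation, n = 12, which wants ≥ 13 years. Both options exist because
  short or degenerate series otherwise make Σ singular.

## Pipeline conventions

- **City future climate** is the unweighted mean over valid future-grid
  cells whose centers fall inside the urban polygon (`polygon_mean`);
  a `centroid` mode exists for sensitivity checks. The contemporary analog
  pool is never resampled — future values may come from a finer grid.
- **Ensembles.** Climate variables are averaged across members per
  trajectory before the statistic. Averaging sigma instead is not reachable
  through the pipeline's public surface, and a constructed counterexample
  in the test suite demonstrates the two orders genuinely differ.
- **Best analog.** Argmin of σ over valid cells; exact ties break by
  row-major scan order of the stored surface, with the tie count surfaced.
- **Geodesy.** Great-circle distance (haversine) and initial bearing
  (forward azimuth, [0, 360)) on a sphere of radius 6371.0088 km; spherical
  error is far below one grid cell at analog distances. Coincident
  city/analog points return (0 km, 0°) flagged degenerate and are excluded
  (and counted) in bearing summaries.
- **Summaries.** Distances average arithmetically; bearings use the
  circular (resultant-vector) mean, since arithmetic angle means fail under
  wraparound.
- **Filters.** Urban areas must exceed 50 km², pass a station-availability
  check, and — when a pool is supplied — intersect ≥ 2 distinct valid pool
  cells as a minimal spatial-heterogeneity proxy. Each exclusion carries a
  machine-readable reason. Per-city failures quarantine the city; the run
  continues and reports them.
- **Domain crop.** Cell membership is by cell center, half-open
  (min ≤ center < max) so adjacent boxes tile without double counting;
  `ClimateGrid.extent` gives the edge-based bounds for which cropping is
  the identity.

## Synthetic world

The generators emulate the *structure* of the real inputs, not their
climatology:

- **Grids.** Temperature = base − 0.6 °C/° latitude ± 10 °C seasonal
  amplitude, tmax = tmin + 9 °C, precipitation = 150 mm + 8 mm/° longitude;
  i.i.d. Gaussian cell noise (0.5 °C, 15 mm), precipitation truncated at 0;
  10% of cells masked as ocean. Defaults chosen once as a plausible
  mid-latitude continental gradient.
- **Planted analogs.** A future vector copied from a known cell (plus a
  known offset) must be recovered cell-exactly at 0σ — the ground truth for
  the recovery tests.
- **Stations.** Annual seasonal 12-vectors drawn from a known covariance
  (shared across stations so the city-level signal survives IDW),
  disaggregated to months with small noise (0.2 °C; precipitation split
  30/35/35% per season, 2 mm noise, truncated at 0). December is written to
  the preceding calendar year so lagged-DJF aggregation reassembles the
  draws. The monthly disaggregation is test plumbing: its noise is kept
  small so seasonal re-aggregation recovers the drawn vectors to within the
  tested tolerances.

What a green synthetic run establishes: the statistic is calibrated, the
estimators recover planted parameters, and the pipeline wiring (selection,
IDW, aggregation, ensembles, argmin, geodesy, exports) is correct. What it
does not establish: anything about real climatologies — there is no
topography, no spatial noise correlation, no heavy-tailed precipitation, no
model-ensemble structure beyond additive offsets.

## Known limitations

- The real-data inputs (5-arc-minute normals, downscaled 2080s projections
  for 27 models × 2 trajectories, station archives, urban shapefiles) are
  external downloads; the package reads their formats (netCDF, CSV,
  GeoJSON) but ships none of them, so published continental-scale numbers
  are not reproduced here.
- Raster I/O is netCDF only (no GeoTIFF reader/writer in this
  environment); polygons are GeoJSON only (no shapefile reader).
- The spatial-heterogeneity filter is a cell-count proxy; the original
  criterion was never quantified, and on grids much coarser than 5 arc
  minutes the proxy is inapplicable (supply a custom check instead).
- No urban-heat-island, sea-level or extreme-event effects; no downscaling
  or bias correction — future grids are consumed as given.
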