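"""Synthetic inputs with known structure for every pipeline stage.

Real inputs (gridded climate normals, downscaled future projections, station
records, urban polygons) are large external downloads; the generators here
emulate their statistical structure so every stage of the pipeline is
testable end to end without any network access:

* smooth climate grids — temperature falls with latitude (a lapse),
  precipitation follows a longitude gradient, plus Gaussian noise and an
  "ocean" mask;
* planted analogs — a future climate vector copied from a known target cell
  (plus a known offset), which the pipeline must recover;
* station series — annual seasonal 12-vectors drawn from a known 12×12
  covariance, disaggregated to months, so the ICV estimator can be checked
  for parameter recovery;
* square urban polygons of known area.

All generators are pure functions of (config, seed). The generated world is
deliberately simple: Gaussian noise everywhere (precipitation truncated at
zero), no topography, no heavier-tailed precipitation, no spatial
autocorrelation in the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grids import VARIABLE_KEYS, ClimateGrid, SeasonalClimateVector, UrbanArea
from .stations import StationSeries

#: Seasonal temperature phase (Northern-Hemisphere convention).
_SEASON_PHASE = {"DJF": -1.0, "MAM": 0.0, "JJA": 1.0, "SON": 0.0}
#: Fixed within-season monthly split of precipitation totals.
_PRCP_SPLIT = (0.30, 0.35, 0.35)

_KM_PER_DEG = 111.19492664455873


@dataclass(frozen=True)
class PlantedCity:
    """A synthetic city with a known best-analog target cell."""

    name: str
    center: tuple[float, float]  # (lat, lon)
    target_cell: tuple[int, int]  # (row, col) in the grid
    offset: tuple[float, ...] = tuple([0.0] * 12)
    area_km2: float = 100.0


@dataclass(frozen=True)
class SyntheticConfig:
    """The stated synthetic world; every generated artifact records its seed.

    Defaults describe a mid-latitude continental domain: a 0.6 °C per degree
    latitude temperature lapse, ±10 °C seasonal cycle, a 9 °C diurnal-range
    spread between tmin and tmax, an 8 mm per degree longitude precipitation
    gradient on a 150 mm seasonal base, and modest cell-level noise
    (0.5 °C, 15 mm).
    """

    shape: tuple[int, int] = (30, 40)  # n_lat × n_lon
    bbox: tuple[float, float, float, float] = (20.0, 60.0, -130.0, -60.0)
    base_tmin: float = 22.0  # °C at 0° latitude, mean season
    lapse: float = 0.6  # °C per degree latitude
    seasonal_amplitude: float = 10.0  # °C
    diurnal_spread: float = 9.0  # tmax − tmin, °C
    base_prcp: float = 150.0  # mm per season at the west edge
    prcp_gradient: float = 8.0  # mm per degree longitude
    noise_sd_temp: float = 0.5  # °C
    noise_sd_prcp: float = 15.0  # mm
    ocean_fraction: float = 0.1
    seed: int = 0
    planted_cities: tuple[PlantedCity, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.shape[0] < 2 or self.shape[1] < 2:
            raise ValueError("grid shape must be at least 2×2")
        if self.noise_sd_temp < 0 or self.noise_sd_prcp < 0:
            raise ValueError("noise sd must be nonnegative")


def make_grid(cfg: SyntheticConfig) -> ClimateGrid:
    """Generate a smooth, noisy climate grid, reproducible from the seed.

    tmin = base − lapse·lat + amplitude·phase(season) + noise;
    tmax = tmin-signal + diurnal spread + its own noise;
    prcp = max(0, base + gradient·(lon − west edge) + noise).
    A random ``ocean_fraction`` of cells is masked.
    """
    rng = np.random.default_rng(cfg.seed)
    nlat, nlon = cfg.shape
    lat_min, lat_max, lon_min, lon_max = cfg.bbox
    dlat = (lat_max - lat_min) / nlat
    dlon = (lon_max - lon_min) / nlon
    lat = lat_min + dlat * (np.arange(nlat) + 0.5)
    lon = lon_min + dlon * (np.arange(nlon) + 0.5)
    lat2d = lat[:, None] * np.ones((1, nlon))
    lon2d = np.ones((nlat, 1)) * lon[None, :]

    data = np.empty((12, nlat, nlon))
    for k, key in enumerate(VARIABLE_KEYS):
        var, season = key.split("_")
        if var == "prcp":
            base = cfg.base_prcp + cfg.prcp_gradient * (lon2d - lon_min)
            noise = rng.normal(0.0, cfg.noise_sd_prcp, (nlat, nlon)) if cfg.noise_sd_prcp else 0.0
            data[k] = np.clip(base + noise, 0.0, None)
        else:
            signal = (
                cfg.base_tmin
                - cfg.lapse * lat2d
                + cfg.seasonal_amplitude * _SEASON_PHASE[season]
            )
            if var == "tmax":
                signal = signal + cfg.diurnal_spread
            noise = rng.normal(0.0, cfg.noise_sd_temp, (nlat, nlon)) if cfg.noise_sd_temp else 0.0
            data[k] = signal + noise

    mask = np.ones((nlat, nlon), dtype=bool)
    if cfg.ocean_fraction > 0:
        n_masked = int(round(cfg.ocean_fraction * nlat * nlon))
        flat = rng.choice(nlat * nlon, size=n_masked, replace=False)
        mask.ravel()[flat] = False
    return ClimateGrid(
        data=data,
        lat=lat,
        lon=lon,
        mask=mask,
        metadata={"seed": cfg.seed, "synthetic": True},
    )


def plant_future(
    grid: ClimateGrid, target_cell: tuple[int, int], offset=None
) -> SeasonalClimateVector:
    """Future climate vector equal to a target cell's climate plus an offset.

    With a zero offset the pipeline must recover ``target_cell`` as the best
    analog at exactly 0σ, making this the ground truth for recovery tests.
    """
    i, j = target_cell
    vec = grid.vector_at(i, j)  # raises CoverageError on a masked target
    if offset is None:
        return vec
    return vec.shifted(np.asarray(offset, dtype=float))


def default_icv_truth() -> tuple[np.ndarray, np.ndarray]:
    """A realistic ICV ground truth: means plus an exponential-decay correlation.

    Interannual standard deviations of ~1 °C for seasonal temperatures and
    ~40 mm for seasonal totals, with correlation 0.4^|i−j| across the
    canonical variable ordering (a simple PSD structure giving neighbouring
    seasons and paired tmin/tmax moderate dependence).
    """
    mean = np.array(
        [5.0, 12.0, 22.0, 13.0, 14.0, 21.0, 31.0, 22.0, 220.0, 260.0, 280.0, 240.0]
    )
    sd = np.array([1.0] * 8 + [40.0] * 4)
    idx = np.arange(12)
    corr = 0.4 ** np.abs(idx[:, None] - idx[None, :])
    cov = corr * np.outer(sd, sd)
    return mean, cov


def make_station_series(
    mean: np.ndarray,
    covariance: np.ndarray,
    n_years: int = 31,
    n_stations: int = 5,
    jitter_km: float = 10.0,
    seed: int = 0,
    center: tuple[float, float] = (39.0, -77.0),
    start_year: int = 1960,
    monthly_noise_sd_temp: float = 0.2,
    monthly_noise_sd_prcp: float = 2.0,
) -> list[StationSeries]:
    """Monthly station records whose seasonal aggregation has known covariance.

    Annual seasonal 12-vectors are drawn i.i.d. from MVN(mean, covariance) —
    one shared draw per year across stations, so the city-level signal
    survives inverse-distance combination — then disaggregated to months:
    each temperature month is its season's value plus small i.i.d. noise,
    each precipitation season total splits into fixed monthly proportions
    plus noise (truncated at zero). December is written to the *preceding*
    calendar year so the lagged-DJF seasonal aggregation reassembles the
    drawn vectors. Station locations jitter around the center.

    The monthly tables cover ``start_year .. start_year + n_years − 1``
    completely, so ``n_years = 31`` emulates the 1960–1990 window and yields
    30 complete seasonal years downstream.
    """
    covariance = np.asarray(covariance, dtype=float)
    eigmin = np.linalg.eigvalsh((covariance + covariance.T) / 2).min()
    if eigmin < -1e-8 * max(np.abs(covariance).max(), 1.0):
        raise ValueError("covariance must be positive semi-definite")
    if n_years < 2:
        raise ValueError("n_years must be at least 2")
    rng = np.random.default_rng(seed)
    end_year = start_year + n_years - 1
    # season-years start_year .. end_year+1: DJF(Y) fills Dec(Y−1), Jan(Y), Feb(Y)
    annual = rng.multivariate_normal(mean, covariance, size=n_years + 1)
    key_idx = {k: i for i, k in enumerate(VARIABLE_KEYS)}

    # one calendar row per (year, month); December belongs to next year's DJF
    years = np.repeat(np.arange(start_year, end_year + 1), 12)
    months = np.tile(np.arange(1, 13), n_years)
    season_of = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                 6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}
    pos_of = {12: 0, 1: 1, 2: 2, 3: 0, 4: 1, 5: 2, 6: 0, 7: 1, 8: 2,
              9: 0, 10: 1, 11: 2}
    si = years - start_year + (months == 12)
    season_keys = {
        var: np.array([key_idx[f"{var}_{season_of[m]}"] for m in months[:12]])
        for var in ("tmin", "tmax", "prcp")
    }
    prcp_split = np.array([_PRCP_SPLIT[pos_of[m]] for m in months[:12]])
    n_rows = years.size

    stations = []
    for s in range(n_stations):
        lat = center[0] + rng.normal(0.0, jitter_km / _KM_PER_DEG)
        lon = center[1] + rng.normal(
            0.0, jitter_km / (_KM_PER_DEG * np.cos(np.radians(center[0])))
        )
        cols = {"year": years, "month": months}
        for var in ("tmin", "tmax"):
            signal = annual[si, np.tile(season_keys[var], n_years)]
            cols[var] = signal + rng.normal(0.0, monthly_noise_sd_temp, n_rows)
        totals = annual[si, np.tile(season_keys["prcp"], n_years)]
        cols["prcp"] = np.clip(
            totals * np.tile(prcp_split, n_years)
            + rng.normal(0.0, monthly_noise_sd_prcp, n_rows),
            0.0,
            None,
        )
        stations.append(
            StationSeries(
                station_id=f"SYN{s:03d}",
                lat=float(lat),
                lon=float(lon),
                table=pd.DataFrame(cols),
            )
        )
    return stations


def make_urban_polygon(
    center: tuple[float, float],
    area_km2: float,
    shape: str = "square",
    name: str = "city",
) -> UrbanArea:
    """Square urban polygon of the requested area centered at (lat, lon)."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    if shape != "square":
        raise ValueError(f"unknown polygon shape {shape!r}")
    lat, lon = center
    side_km = float(np.sqrt(area_km2))
    half_lat = side_km / 2 / _KM_PER_DEG
    half_lon = side_km / 2 / (_KM_PER_DEG * np.cos(np.radians(lat)))
    polygon = shapely.box(lon - half_lon, lat - half_lat, lon + half_lon, lat + half_lat)
    return UrbanArea(name=name, centroid=(lat, lon), area_km2=area_km2, polygon=polygon)
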