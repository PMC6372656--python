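"""Gridded climate data: the 12 seasonal variables, grids, cities, ensembles.

The climate state of one place/time is a 12-vector: minimum and maximum
temperature (°C) and total precipitation (mm) for each climatological season
(DJF, MAM, JJA, SON). A :class:`ClimateGrid` holds those 12 layers on a
regular lat/lon grid of cell centers with a shared validity mask; it serves
both as the contemporary analog pool and as a future climate surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely

from .errors import ConfigurationError, CoverageError, DomainError, GeometryError

SEASONS: tuple[str, ...] = ("DJF", "MAM", "JJA", "SON")
VARIABLES: tuple[str, ...] = ("tmin", "tmax", "prcp")
#: Canonical ordering of the 12 climate variables (variable-major).
VARIABLE_KEYS: tuple[str, ...] = tuple(f"{v}_{s}" for v in VARIABLES for s in SEASONS)

#: Months (1-based) belonging to each season; DJF = Dec, Jan, Feb.
SEASON_MONTHS: dict[str, tuple[int, int, int]] = {
    "DJF": (12, 1, 2),
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
}


def _key_index(key: str) -> int:
    try:
        return VARIABLE_KEYS.index(key)
    except ValueError:
        raise KeyError(f"unknown climate variable key {key!r}; expected one of {VARIABLE_KEYS}")


@dataclass(frozen=True)
class SeasonalClimateVector:
    """The 12-dimensional seasonal climate state of one place and time.

    ``values`` follows :data:`VARIABLE_KEYS` order: tmin then tmax (°C,
    seasonal means) then prcp (mm, seasonal totals), each over DJF, MAM,
    JJA, SON.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError(f"expected 12 values, got shape {v.shape}")
        object.__setattr__(self, "values", v)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "SeasonalClimateVector":
        missing = set(VARIABLE_KEYS) - set(mapping)
        if missing:
            raise ConfigurationError(f"missing climate variables: {sorted(missing)}")
        return cls(np.array([mapping[k] for k in VARIABLE_KEYS], dtype=float))

    def to_dict(self) -> dict[str, float]:
        return {k: float(x) for k, x in zip(VARIABLE_KEYS, self.values)}

    def __getitem__(self, key: str) -> float:
        return float(self.values[_key_index(key)])

    def validate(self) -> None:
        """Check physical invariants: finiteness, tmax ≥ tmin, prcp ≥ 0."""
        if not np.all(np.isfinite(self.values)):
            raise ValueError("climate vector contains non-finite values")
        for s in SEASONS:
            if self[f"tmax_{s}"] < self[f"tmin_{s}"]:
                raise ValueError(f"tmax < tmin in season {s}")
            if self[f"prcp_{s}"] < 0:
                raise ValueError(f"negative precipitation in season {s}")

    def shifted(self, offset: np.ndarray) -> "SeasonalClimateVector":
        return SeasonalClimateVector(self.values + np.asarray(offset, dtype=float))


@dataclass
class ClimateGrid:
    """Regular lat/lon raster of the 12 seasonal layers plus a validity mask.

    ``data`` has shape (12, nlat, nlon) in :data:`VARIABLE_KEYS` order;
    ``lat``/``lon`` are strictly monotone cell-center coordinate vectors in
    degrees. ``mask`` is True on usable (land) cells; masked cells are NaN
    in every layer. Latitude may be stored north→south or south→north — the
    coordinate vectors are authoritative, so orientation never matters to
    callers.
    """

    data: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        nlat, nlon = self.lat.size, self.lon.size
        if self.data.shape != (12, nlat, nlon):
            raise GeometryError(
                f"data shape {self.data.shape} does not match (12, {nlat}, {nlon})"
            )
        if self.mask.shape != (nlat, nlon):
            raise GeometryError("mask shape does not match coordinates")
        for name, coord in (("lat", self.lat), ("lon", self.lon)):
            d = np.diff(coord)
            if coord.size > 1:
                if not (np.all(d > 0) or np.all(d < 0)):
                    raise GeometryError(f"{name} coordinates are not strictly monotone")
                if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                    raise GeometryError(f"{name} spacing is not constant")
        # masked cells carry no finite values in any layer
        self.data[:, ~self.mask] = np.nan

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def cell_size(self) -> tuple[float, float]:
        """(dlat, dlon) spacing magnitudes in degrees."""
        dlat = abs(float(self.lat[1] - self.lat[0])) if self.lat.size > 1 else 0.0
        dlon = abs(float(self.lon[1] - self.lon[0])) if self.lon.size > 1 else 0.0
        return dlat, dlon

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Edge-based bounds (lat_min, lat_max, lon_min, lon_max)."""
        dlat, dlon = self.cell_size
        return (
            float(self.lat.min()) - dlat / 2,
            float(self.lat.max()) + dlat / 2,
            float(self.lon.min()) - dlon / 2,
            float(self.lon.max()) + dlon / 2,
        )

    def layer(self, key: str) -> np.ndarray:
        return self.data[_key_index(key)]

    def vector_at(self, i: int, j: int) -> SeasonalClimateVector:
        """Climate 12-vector of the cell at row ``i``, column ``j``."""
        if not self.mask[i, j]:
            raise CoverageError(f"cell ({i}, {j}) is masked")
        return SeasonalClimateVector(self.data[:, i, j].copy())

    def valid_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """All valid-cell climates as (N, 12) plus their flat row-major indices."""
        flat = self.mask.ravel()
        idx = np.flatnonzero(flat)
        vals = self.data.reshape(12, -1)[:, idx].T
        return vals, idx

    def same_geometry(self, other: "ClimateGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat, other.lat, atol=atol)
            and np.allclose(self.lon, other.lon, atol=atol)
        )


@dataclass
class UrbanArea:
    """A named city: polygon (lon/lat ring, optional), centroid, area.

    ``centroid`` is (lat, lon) in degrees; the polygon, when present, uses
    shapely's (x, y) = (lon, lat) convention.
    """

    name: str
    centroid: tuple[float, float]
    area_km2: float
    polygon: shapely.Polygon | None = None

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"{self.name}: area_km2 must be positive")
        if self.polygon is not None:
            lat, lon = self.centroid
            minx, miny, maxx, maxy = self.polygon.bounds
            if not (miny <= lat <= maxy and minx <= lon <= maxx):
                raise ValueError(f"{self.name}: centroid outside polygon bounding box")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def monthly_to_seasonal(monthly: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Aggregate 12 monthly layers per variable to the 4 climatological seasons.

    ``monthly`` maps each variable ('tmin', 'tmax', 'prcp') to an array with
    leading dimension 12 (January..December). Temperatures aggregate as the
    3-month mean, precipitation as the 3-month total; DJF combines December,
    January, February of the same climatology (normals carry no year axis).
    """
    out: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        if var not in monthly:
            raise ConfigurationError(f"missing monthly layers for variable {var!r}")
        arr = np.asarray(monthly[var], dtype=float)
        if arr.shape[0] != 12:
            raise ConfigurationError(
                f"variable {var!r} needs 12 monthly layers, got {arr.shape[0]}"
            )
        for season, months in SEASON_MONTHS.items():
            stack = arr[[m - 1 for m in months]]
            agg = stack.sum(axis=0) if var == "prcp" else stack.mean(axis=0)
            out[f"{var}_{season}"] = agg
    return out


def crop_domain(
    grid: ClimateGrid, bbox: tuple[float, float, float, float]
) -> ClimateGrid:
    """Crop a grid to the cells whose centers fall inside a lat/lon bbox.

    ``bbox`` is (lat_min, lat_max, lon_min, lon_max) in degrees. Selection is
    half-open on cell centers (min ≤ center < max) so adjacent boxes tile the
    grid without double counting; :attr:`ClimateGrid.extent` gives edge-based
    bounds for which the crop is the identity.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    rows = np.flatnonzero((grid.lat >= lat_min) & (grid.lat < lat_max))
    cols = np.flatnonzero((grid.lon >= lon_min) & (grid.lon < lon_max))
    if rows.size == 0 or cols.size == 0:
        raise DomainError(f"bbox {bbox} does not intersect the grid")
    return ClimateGrid(
        data=grid.data[:, rows[:, None], cols[None, :]].copy(),
        lat=grid.lat[rows].copy(),
        lon=grid.lon[cols].copy(),
        mask=grid.mask[rows[:, None], cols[None, :]].copy(),
        metadata={**grid.metadata, "bbox": bbox},
    )


def ensemble_mean(members: Sequence[ClimateGrid | SeasonalClimateVector]):
    """Per-variable arithmetic mean across ensemble members.

    This is the *variables-first* ensemble: future climate variables are
    averaged across earth-system-model members before any dissimilarity is
    computed. Sigma values themselves are never averaged anywhere in the
    pipeline. Grid members must share geometry; the output mask keeps only
    cells valid in every member.
    """
    members = list(members)
    if not members:
        raise ValueError("ensemble_mean needs at least one member")
    first = members[0]
    if isinstance(first, SeasonalClimateVector):
        if not all(isinstance(m, SeasonalClimateVector) for m in members):
            raise TypeError("mixed ensemble member types")
        return SeasonalClimateVector(
            np.mean([m.values for m in members], axis=0)
        )
    for m in members[1:]:
        if not first.same_geometry(m):
            raise GeometryError("ensemble members do not share grid geometry")
    mask = np.logical_and.reduce([m.mask for m in members])
    data = np.mean([m.data for m in members], axis=0)
    return ClimateGrid(
        data=data,
        lat=first.lat.copy(),
        lon=first.lon.copy(),
        mask=mask,
        metadata={**first.metadata, "ensemble_n": len(members)},
    )


def extract_city_climate(
    grid: ClimateGrid, city: UrbanArea, mode: str = "polygon_mean"
) -> SeasonalClimateVector:
    """Extract a city's 12-variable climate from a grid.

    ``polygon_mean`` (default): unweighted mean over valid cells whose centers
    fall inside the city polygon. ``centroid``: value of the cell containing
    the centroid. The analog pool is never resampled; the city climate may
    come from a finer future grid than the pool.
    """
    if mode == "centroid":
        lat, lon = city.centroid
        i = int(np.argmin(np.abs(grid.lat - lat)))
        j = int(np.argmin(np.abs(grid.lon - lon)))
        dlat, dlon = grid.cell_size
        if abs(grid.lat[i] - lat) > dlat / 2 + 1e-12 or abs(grid.lon[j] - lon) > dlon / 2 + 1e-12:
            raise CoverageError(f"{city.name}: centroid outside the grid")
        if not grid.mask[i, j]:
            raise CoverageError(f"{city.name}: centroid cell is masked")
        return grid.vector_at(i, j)
    if mode != "polygon_mean":
        raise ValueError(f"unknown extraction mode {mode!r}")
    if city.polygon is None:
        raise ConfigurationError(f"{city.name}: polygon_mean extraction needs a polygon")
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    pts = shapely.points(lon2d.ravel(), lat2d.ravel())
    inside = shapely.contains(city.polygon, pts).reshape(grid.shape)
    sel = inside & grid.mask
    if not sel.any():
        raise CoverageError(f"{city.name}: no valid grid cell inside the polygon")
    return SeasonalClimateVector(grid.data[:, sel].mean(axis=1))


def city_pool_cell_count(grid: ClimateGrid, city: UrbanArea) -> int:
    """Number of distinct valid cells of ``grid`` intersected by the city.

    Used by the urban-area filter as a minimal spatial-heterogeneity proxy:
    a city whose polygon covers < 2 distinct valid cells cannot exhibit
    within-city climatic variation on this grid. Falls back to the centroid
    cell (0 or 1) when no polygon is present.
    """
    if city.polygon is None:
        try:
            extract_city_climate(grid, city, mode="centroid")
            return 1
        except CoverageError:
            return 0
    lon2d, lat2d = np.meshgrid(grid.lon, grid.lat)
    pts = shapely.points(lon2d.ravel(), lat2d.ravel())
    inside = shapely.contains(city.polygon, pts).reshape(grid.shape)
    return int((inside & grid.mask).sum())
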