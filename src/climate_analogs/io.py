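"""File formats: netCDF grids, GeoJSON urban areas and analog layers, CSV.

Gridded climate data travels as CF-style netCDF (lat/lon coordinate
variables, one data variable per layer); the mapping from layer names to the
12 canonical climate variables — including any packed-integer scale/offset —
is declared by the caller, never guessed. Urban-area polygons are GeoJSON.
Analog results export as CSV (one row per city × scenario) and as a GeoJSON
layer with city points, analog points, and connecting lines, ready for a web
map.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import shape as shapely_shape

from .errors import ConfigurationError, GeometryError
from .grids import VARIABLE_KEYS, ClimateGrid, UrbanArea
from .pipeline import AnalogResult, SimilaritySurface, results_to_dataframe

#: variable_map entry: layer name -> (variable, season, scale, offset)
VariableMap = Mapping[str, tuple[str, str, float, float]]


def _open_dataset(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    rename = {}
    for cand, target in (("latitude", "lat"), ("longitude", "lon")):
        if cand in ds.coords:
            rename[cand] = target
    return ds.rename(rename) if rename else ds


def read_normals(paths: Sequence, variable_map: VariableMap) -> ClimateGrid:
    """Assemble a :class:`ClimateGrid` from netCDF layer files.

    ``variable_map`` maps each netCDF data-variable name to
    ``(variable, season, scale, offset)``; physical value = stored × scale +
    offset, so packed storage (e.g. temperature in tenths of °C, scale 0.1)
    must be declared here. All layers must share grid geometry; the validity
    mask is the union of per-layer nodata (a cell missing in any layer is
    masked in all). The map must cover the 12 canonical variables exactly
    once.
    """
    targets = {}
    for layer, (var, season, scale, offset) in variable_map.items():
        key = f"{var}_{season}"
        if key not in VARIABLE_KEYS:
            raise ConfigurationError(f"unknown variable/season {key!r}")
        if key in targets:
            raise ConfigurationError(f"variable {key!r} mapped more than once")
        targets[key] = (layer, float(scale), float(offset))
    missing = set(VARIABLE_KEYS) - set(targets)
    if missing:
        raise ConfigurationError(f"variable_map misses {sorted(missing)}")

    layers: dict[str, np.ndarray] = {}
    lat = lon = None
    for path in paths:
        with _open_dataset(path) as ds:
            if "lat" not in ds.coords or "lon" not in ds.coords:
                raise GeometryError(f"{path}: no lat/lon coordinates")
            if lat is None:
                lat = ds["lat"].values.astype(float)
                lon = ds["lon"].values.astype(float)
            elif not (
                ds["lat"].size == lat.size
                and ds["lon"].size == lon.size
                and np.allclose(ds["lat"].values, lat)
                and np.allclose(ds["lon"].values, lon)
            ):
                raise GeometryError(f"{path}: grid geometry differs from other layers")
            for name in ds.data_vars:
                if name in (set(v[0] for v in targets.values())):
                    layers[str(name)] = (
                        ds[name].transpose("lat", "lon").values.astype(float)
                    )
    data = np.empty((12, lat.size, lon.size))
    mask = np.ones((lat.size, lon.size), dtype=bool)
    for k, key in enumerate(VARIABLE_KEYS):
        layer, scale, offset = targets[key]
        if layer not in layers:
            raise ConfigurationError(f"layer {layer!r} (for {key}) not found in inputs")
        vals = layers[layer] * scale + offset
        mask &= np.isfinite(vals)
        data[k] = vals
    return ClimateGrid(data=data, lat=lat, lon=lon, mask=mask)


def grid_to_dataset(grid: ClimateGrid) -> xr.Dataset:
    ds = xr.Dataset(
        {k: (("lat", "lon"), grid.data[i]) for i, k in enumerate(VARIABLE_KEYS)},
        coords={"lat": grid.lat, "lon": grid.lon},
        attrs={str(k): str(v) for k, v in grid.metadata.items()},
    )
    for k in VARIABLE_KEYS:
        ds[k].attrs["units"] = "mm" if k.startswith("prcp") else "degC"
    return ds


def write_normals(grid: ClimateGrid, path) -> None:
    """Write a grid as CF-style netCDF; finite cells round-trip bit-for-bit."""
    grid_to_dataset(grid).to_netcdf(path, engine="scipy")


def surface_to_netcdf(surface: SimilaritySurface, path) -> None:
    """Export a sigma similarity surface as a single-variable netCDF layer."""
    ds = xr.Dataset(
        {"sigma": (("lat", "lon"), surface.sigma.astype(np.float32))},
        coords={"lat": surface.lat, "lon": surface.lon},
        attrs={"city": surface.city, "scenario": surface.scenario, "dof": surface.dof},
    )
    ds["sigma"].attrs.update(long_name="sigma dissimilarity", units="sigma")
    ds.to_netcdf(path, engine="scipy")


def write_results_csv(results: Sequence[AnalogResult], path) -> None:
    results_to_dataframe(results).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# GeoJSON
# ---------------------------------------------------------------------------

_KM_PER_DEG = 111.19492664455873  # spherical degree of latitude, R = 6371.0088


def read_urban_areas_geojson(path, name_field: str = "name") -> list[UrbanArea]:
    """Read urban-area polygons from GeoJSON.

    Uses an ``area_km2`` property when present, otherwise approximates the
    polygon area on the sphere from its degree-space area scaled by
    cos(centroid latitude) — adequate for the >50 km² inclusion filter.
    """
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        props = feat.get("properties", {})
        name = str(props.get(name_field, f"area_{len(out)}"))
        c = geom.centroid
        area = props.get("area_km2")
        if area is None:
            area = geom.area * _KM_PER_DEG**2 * np.cos(np.radians(c.y))
        out.append(
            UrbanArea(name=name, centroid=(c.y, c.x), area_km2=float(area), polygon=geom)
        )
    return out


def write_urban_areas_geojson(cities: Sequence[UrbanArea], path) -> None:
    features = []
    for city in cities:
        geom = city.polygon
        if geom is None:
            geom = shapely.Point(city.centroid[1], city.centroid[0])
        features.append(
            {
                "type": "Feature",
                "geometry": json.loads(shapely.to_geojson(geom)),
                "properties": {"name": city.name, "area_km2": city.area_km2},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def results_to_geojson(
    results: Sequence[AnalogResult],
    cities: Mapping[str, UrbanArea],
    path=None,
) -> dict:
    """Web-map layer: city point, best-analog point, and connecting line.

    Each result contributes three features sharing sigma, class, distance,
    and bearing properties. Returns the FeatureCollection dict and writes it
    to ``path`` when given.
    """
    features = []
    for r in results:
        city = cities[r.city]
        props = {
            "city": r.city,
            "scenario": r.scenario,
            "sigma": r.min_sigma,
            "analog_class": r.analog_class,
            "distance_km": r.distance_km,
            "bearing_deg": r.bearing_deg,
        }
        city_pt = [city.centroid[1], city.centroid[0]]
        analog_pt = [r.best_lon, r.best_lat]
        for geom, role in (
            ({"type": "Point", "coordinates": city_pt}, "city"),
            ({"type": "Point", "coordinates": analog_pt}, "analog"),
            ({"type": "LineString", "coordinates": [city_pt, analog_pt]}, "link"),
        ):
            features.append(
                {"type": "Feature", "geometry": geom, "properties": {**props, "role": role}}
            )
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection
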