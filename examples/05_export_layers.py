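"""Round-trip the file formats: netCDF grids and surfaces, CSV, GeoJSON.

Writes a synthetic climate grid to CF-style netCDF and reads it back through
the declared variable map, exports a sigma similarity surface, a results
CSV, and the web-map GeoJSON layer (city point, analog point, link line).
All outputs land in a temporary directory.
"""

import json
import tempfile
from pathlib import Path

import numpy as np

from climate_analogs import (
    ICVModel,
    VARIABLE_KEYS,
    best_analog,
    read_normals,
    results_to_geojson,
    similarity_surface,
    surface_to_netcdf,
    write_normals,
    write_results_csv,
)
from climate_analogs.synthetic import SyntheticConfig, make_grid, make_urban_polygon, plant_future

out = Path(tempfile.mkdtemp(prefix="analog_layers_"))
grid = make_grid(SyntheticConfig(seed=3))

write_normals(grid, out / "normals.nc")
variable_map = {k: (*k.split("_"), 1.0, 0.0) for k in VARIABLE_KEYS}
back = read_normals([out / "normals.nc"], variable_map)
print("netCDF round-trip exact:", np.array_equal(back.data[:, back.mask], grid.data[:, grid.mask]))

icv = ICVModel(mean=np.zeros(12), covariance=np.eye(12), retained_dims=12)
city = make_urban_polygon((40.0, -95.0), 150.0, name="Demo City")
surf = similarity_surface(plant_future(grid, (20, 20)), grid, icv,
                          city=city.name, scenario="demo")
res = best_analog(surf, city)

surface_to_netcdf(surf, out / "surface.nc")
write_results_csv([res], out / "results.csv")
layer = results_to_geojson([res], {city.name: city}, out / "layer.geojson")

print(f"wrote {sorted(p.name for p in out.iterdir())} to {out}")
print(f"GeoJSON features: {[f['properties']['role'] for f in layer['features']]}")
print(json.dumps(layer["features"][2]["properties"], indent=2))
# The link feature carries everything a web map needs to draw the
# city-to-analog arrow with its sigma, class, distance and bearing.
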