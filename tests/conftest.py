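import numpy as np
import pytest

from climate_analogs import ClimateGrid, ICVModel, SeasonalClimateVector, VARIABLE_KEYS


@pytest.fixture
def identity_icv() -> ICVModel:
    """ICV with unit variance and no correlation: Mahalanobis = Euclidean."""
    return ICVModel(mean=np.zeros(12), covariance=np.eye(12), retained_dims=12)


@pytest.fixture
def flat_grid_factory():
    """Grids with hand-set layer values on a small regular lat/lon raster."""

    def make(nlat=4, nlon=5, fill=10.0, lat0=30.0, lon0=-100.0, step=1.0, mask=None):
        data = np.full((12, nlat, nlon), float(fill))
        # keep physical invariants: bump tmax above tmin, keep prcp positive
        for k, key in enumerate(VARIABLE_KEYS):
            if key.startswith("tmax"):
                data[k] += 8.0
        lat = lat0 + step * np.arange(nlat)
        lon = lon0 + step * np.arange(nlon)
        if mask is None:
            mask = np.ones((nlat, nlon), dtype=bool)
        return ClimateGrid(data=data, lat=lat, lon=lon, mask=mask)

    return make


@pytest.fixture
def vector_factory():
    def make(value=0.0, **overrides) -> SeasonalClimateVector:
        d = {k: float(value) for k in VARIABLE_KEYS}
        d.update(overrides)
        return SeasonalClimateVector.from_dict(d)

    return make
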