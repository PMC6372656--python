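"""Great-circle distance and initial bearing on a sphere.

Distances between a city and its best analog span hundreds of kilometres on
a 5-arc-minute grid, so spherical geodesy (mean Earth radius 6371.0088 km)
is accurate to far better than one grid cell; ellipsoidal corrections are
deliberately not applied.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


class GeodesicResult(NamedTuple):
    distance_km: float
    bearing_deg: float
    degenerate: bool


def geodesic_distance_bearing(
    origin: tuple[float, float], target: tuple[float, float]
) -> GeodesicResult:
    """Great-circle distance (haversine) and initial bearing (forward azimuth).

    Both points are (lat, lon) in degrees. The bearing is measured clockwise
    from north, normalized to [0, 360). Coincident points return (0, 0) with
    ``degenerate=True``; such results are excluded from circular means.
    """
    lat1, lon1 = origin
    lat2, lon2 = target
    for lat in (lat1, lat2):
        if not np.isfinite(lat) or abs(lat) > 90:
            raise ValueError(f"invalid latitude {lat}")
    if not (np.isfinite(lon1) and np.isfinite(lon2)):
        raise ValueError("invalid longitude")
    if lat1 == lat2 and lon1 == lon2:
        return GeodesicResult(0.0, 0.0, True)

    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = np.radians(lon2 - lon1)

    a = np.sin(dlat / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))

    y = np.sin(dlon) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlon)
    bearing = float(np.degrees(np.arctan2(y, x))) % 360.0
    return GeodesicResult(float(dist), bearing, False)


def circular_mean_deg(bearings: np.ndarray) -> float:
    """Vector-sum mean of bearings in degrees, in [0, 360).

    The arithmetic mean of angles is wrong under wraparound (350° and 10°
    average to 0°, not 180°); the resultant-vector azimuth is the standard
    directional statistic.
    """
    b = np.radians(np.asarray(bearings, dtype=float))
    if b.size == 0:
        raise ValueError("no bearings to average")
    s, c = np.sin(b).mean(), np.cos(b).mean()
    if np.hypot(s, c) < 1e-12:
        raise ValueError("bearings are perfectly balanced; circular mean undefined")
    out = float(np.degrees(np.arctan2(s, c))) % 360.0
    return 0.0 if out >= 360.0 else out  # -eps % 360 rounds up to 360.0
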