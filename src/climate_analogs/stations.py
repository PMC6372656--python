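"""Weather stations, inverse-distance combination, and the ICV model.

Interannual climatic variability (ICV) is the year-to-year covariance of the
12 seasonal climate variables at a city, estimated from monthly station
records over the contemporary reference window (1960–1990 by default). It is
the covariance that standardizes Mahalanobis distances in the sigma
statistic, so each city's dissimilarities are measured relative to the
variability its residents already experience.

Station selection follows the 5-station / 50-km rule: all complete stations
inside the urban-area polygon are used if there are at least five; otherwise
the nearest complete stations within 50 km of the centroid top the set up to
five. Records are combined by inverse-distance weighting toward the
centroid, aggregated to climatological seasons (DJF lagging December from
the previous year), and the sample covariance of the resulting annual
12-vectors is the ICV estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .errors import InsufficientDataError, SingularityError
from .geodesy import geodesic_distance_bearing
from .grids import SEASON_MONTHS, SEASONS, VARIABLE_KEYS, VARIABLES, UrbanArea

#: Contemporary reference window (inclusive years).
DEFAULT_WINDOW: tuple[int, int] = (1960, 1990)

#: Minimum IDW distance, km (1 m floor so a station at the centroid is finite).
MIN_IDW_DISTANCE_KM = 0.001

_MONTH_COLS = ["tmin", "tmax", "prcp"]


@dataclass
class StationSeries:
    """Monthly records of one station (or one IDW-combined pseudo-station).

    ``table`` is long format with columns year, month, tmin, tmax, prcp
    (°C, °C, mm/month), one row per calendar month.
    """

    station_id: str
    lat: float
    lon: float
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"year", "month", *_MONTH_COLS} - set(self.table.columns)
        if missing:
            raise ValueError(f"station {self.station_id}: missing columns {sorted(missing)}")
        self.table = (
            self.table.loc[:, ["year", "month", *_MONTH_COLS]]
            .astype({"year": int, "month": int})
            .sort_values(["year", "month"], kind="stable")
            .reset_index(drop=True)
        )

    def is_complete(self, window: tuple[int, int] = DEFAULT_WINDOW) -> bool:
        """True if no month in the window is missing for any variable."""
        y0, y1 = window
        sub = self.table[(self.table.year >= y0) & (self.table.year <= y1)]
        n_expected = (y1 - y0 + 1) * 12
        if len(sub.drop_duplicates(["year", "month"])) != n_expected:
            return False
        return not sub[_MONTH_COLS].isna().any().any()


@dataclass
class SeasonalSeries:
    """Annual series of seasonal 12-vectors for one city.

    ``table`` is indexed by year with the 12 canonical variable columns;
    every retained year is complete (winter trimming drops the first year
    of the monthly window).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(VARIABLE_KEYS):
            self.table = self.table.loc[:, list(VARIABLE_KEYS)]
        if self.table.isna().any().any():
            raise ValueError("seasonal series contains missing entries")
        if len(self.table) < 2:
            raise InsufficientDataError("seasonal series needs at least 2 years")

    @property
    def n_years(self) -> int:
        return len(self.table)

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class ICVModel:
    """Interannual climatic variability of one city.

    ``covariance`` is expressed in the retained basis: the full 12×12 sample
    covariance when ``basis`` is None, or the diagonal covariance of the
    retained principal axes when PCA truncation was applied (``basis`` then
    holds the orthonormal axes as columns of a 12×n matrix).
    ``retained_dims`` is the chi degrees of freedom ``n`` used by the sigma
    statistic.
    """

    mean: np.ndarray
    covariance: np.ndarray
    retained_dims: int
    basis: np.ndarray | None = None
    detrended: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        k = self.retained_dims
        if not 1 <= k <= 12:
            raise ValueError("retained_dims must be in 1..12")
        if self.covariance.shape != (k, k):
            raise ValueError(f"covariance shape {self.covariance.shape} != ({k}, {k})")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if self.basis is not None:
            self.basis = np.asarray(self.basis, dtype=float)
            if self.basis.shape != (12, k):
                raise ValueError("basis must be 12 × retained_dims")
            if not np.allclose(self.basis.T @ self.basis, np.eye(k), atol=1e-8):
                raise ValueError("basis columns must be orthonormal")


# ---------------------------------------------------------------------------
# Station I/O
# ---------------------------------------------------------------------------

def read_stations_csv(path, na_values=(-9999, -9999.0, "")) -> list[StationSeries]:
    """Read long-format station CSV: station_id, lat, lon, year, month, tmin, tmax, prcp.

    Tolerant of GHCN-style monthly exports using a missing-value sentinel
    (default -9999); sentinel cells become NaN and make a station incomplete.
    """
    df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)
    required = {"station_id", "lat", "lon", "year", "month", *_MONTH_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"station CSV missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("station_id", sort=True):
        out.append(
            StationSeries(
                station_id=str(sid),
                lat=float(grp.lat.iloc[0]),
                lon=float(grp.lon.iloc[0]),
                table=grp[["year", "month", *_MONTH_COLS]],
            )
        )
    return out


def write_stations_csv(stations: Sequence[StationSeries], path) -> None:
    frames = []
    for st in stations:
        t = st.table.copy()
        t.insert(0, "station_id", st.station_id)
        t.insert(1, "lat", st.lat)
        t.insert(2, "lon", st.lon)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Selection and combination
# ---------------------------------------------------------------------------

def _centroid_distance_km(station: StationSeries, centroid: tuple[float, float]) -> float:
    return geodesic_distance_bearing(centroid, (station.lat, station.lon)).distance_km


def select_stations(
    stations: Sequence[StationSeries],
    city: UrbanArea,
    min_n: int = 5,
    max_radius_km: float = 50.0,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[StationSeries]:
    """Select complete stations for a city under the 5-station / 50-km rule.

    All complete stations inside the polygon are returned when they number at
    least ``min_n``; otherwise the nearest complete outside stations within
    ``max_radius_km`` of the centroid are added until ``min_n`` is reached.
    Ordering is deterministic: (centroid distance, station_id). Raises
    :class:`InsufficientDataError` when the rule cannot be satisfied — the
    city is then excluded from further consideration.
    """
    complete = [s for s in stations if s.is_complete(window)]
    with_dist = sorted(
        ((s, _centroid_distance_km(s, city.centroid)) for s in complete),
        key=lambda t: (t[1], t[0].station_id),
    )
    if city.polygon is not None:
        inside = [
            (s, d)
            for s, d in with_dist
            if shapely.contains_xy(city.polygon, s.lon, s.lat)
        ]
    else:
        inside = []
    if len(inside) >= min_n:
        return [s for s, _ in inside]
    chosen = list(inside)
    inside_ids = {s.station_id for s, _ in inside}
    for s, d in with_dist:
        if len(chosen) >= min_n:
            break
        if s.station_id in inside_ids or d > max_radius_km:
            continue
        chosen.append((s, d))
    if len(chosen) < min_n:
        raise InsufficientDataError(
            f"{city.name}: only {len(chosen)} complete stations within "
            f"{max_radius_km} km (need {min_n})"
        )
    chosen.sort(key=lambda t: (t[1], t[0].station_id))
    return [s for s, _ in chosen]


def idw_combine(
    stations: Sequence[StationSeries],
    centroid: tuple[float, float],
    power: float = 1.0,
) -> StationSeries:
    """Inverse-distance-weighted combination of station records at a centroid.

    Weight ``w_i = 1 / d_i^power`` with ``d_i`` the geodesic distance from
    station *i* to the centroid, floored at 1 m so a station sitting exactly
    on the centroid stays finite. Records are combined per year-month over
    the months all stations share.
    """
    if not stations:
        raise ValueError("idw_combine needs at least one station")
    weights = np.array(
        [
            1.0 / max(_centroid_distance_km(s, centroid), MIN_IDW_DISTANCE_KM) ** power
            for s in stations
        ]
    )
    weights = weights / weights.sum()
    tables = [
        s.table.set_index(["year", "month"])[_MONTH_COLS] for s in stations
    ]
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if common.empty:
        raise ValueError("stations share no common year-month records")
    stacked = np.stack([t.loc[common].to_numpy(dtype=float) for t in tables])
    combined = np.einsum("s,sij->ij", weights, stacked)
    out = pd.DataFrame(combined, columns=_MONTH_COLS)
    out.insert(0, "year", common.get_level_values("year"))
    out.insert(1, "month", common.get_level_values("month"))
    return StationSeries(
        station_id="idw_combined", lat=centroid[0], lon=centroid[1], table=out
    )


def monthly_to_seasonal_series(
    series: StationSeries, winter_rule: str = "lagged_december"
) -> SeasonalSeries:
    """Aggregate a monthly series to annual seasonal 12-vectors.

    Temperatures are 3-month means, precipitation 3-month totals. Under
    ``lagged_december`` (the climatological convention and the only rule
    implemented), DJF of year Y combines December of Y−1 with January and
    February of Y, so the first calendar year of the window is dropped and a
    31-year monthly window yields 30 complete seasonal years.
    """
    if winter_rule != "lagged_december":
        raise ValueError(f"unknown winter rule {winter_rule!r}")
    t = series.table
    if t.duplicated(["year", "month"]).any():
        raise ValueError("duplicate year-month rows")
    month_season = {m: s for s, months in SEASON_MONTHS.items() for m in months}
    # December contributes to the *following* year's winter
    season_year = t.year + (t.month == 12).astype(int)
    grouped = t.assign(
        season_year=season_year,
        season=t.month.map(month_season),
        any_nan=t[_MONTH_COLS].isna().any(axis=1),
    ).groupby(["season_year", "season"])
    agg = grouped[_MONTH_COLS].agg({"tmin": "mean", "tmax": "mean", "prcp": "sum"})
    complete = (grouped.size() == 3) & ~grouped["any_nan"].any()
    wide = agg[complete].unstack("season")
    wide.columns = [f"{var}_{season}" for var, season in wide.columns]
    # a retained year needs all four seasons (drops the first year, which has
    # no lagged December, and the season-year after the window's last year)
    wide = wide.dropna().reindex(columns=list(VARIABLE_KEYS))
    if len(wide) < 3:
        raise InsufficientDataError(
            f"only {len(wide)} usable seasonal years after winter trimming (need >= 3)"
        )
    wide.index.name = "year"
    return SeasonalSeries(table=wide.sort_index())


# ---------------------------------------------------------------------------
# ICV estimation
# ---------------------------------------------------------------------------

def _detrend(values: np.ndarray, years: np.ndarray) -> np.ndarray:
    x = years - years.mean()
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        slope, intercept = np.polyfit(x, values[:, j], 1)
        out[:, j] = values[:, j] - (slope * x + intercept) + values[:, j].mean()
    return out


def icv_covariance(
    series: SeasonalSeries,
    detrend: bool = False,
    truncation: float | None = None,
) -> ICVModel:
    """Estimate the ICV model from an annual seasonal series.

    The covariance is the sample covariance (divisor n_years − 1) of the
    annual 12-vectors, optionally after per-variable linear detrending
    (removing a secular trend so it is not counted as interannual
    variability). With ``truncation`` set to a standard-deviation threshold
    *t*, the covariance is re-expressed on its principal axes and only axes
    with standard deviation > *t* are retained (at least one); the retained
    count becomes the chi degrees of freedom ``n``. A full-rank 12×12
    estimate wants n_years ≥ 13; shorter series require truncation.
    """
    values = series.values
    years = series.table.index.to_numpy(dtype=float)
    if detrend:
        values = _detrend(values, years)
    mean = values.mean(axis=0)
    cov = np.cov(values, rowvar=False, ddof=1)
    if truncation is None:
        variances = np.diag(cov)
        if np.any(variances <= 1e-12):
            dead = [VARIABLE_KEYS[i] for i in np.flatnonzero(variances <= 1e-12)]
            raise SingularityError(
                f"zero interannual variance in {dead}; use PCA truncation or add jitter"
            )
        return ICVModel(
            mean=mean,
            covariance=cov,
            retained_dims=12,
            basis=None,
            detrended=detrend,
            metadata={"n_years": series.n_years},
        )
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    eigvals[eigvals < eigvals.max() * 1e-12] = 0.0  # numerically-null axes stay out
    keep = max(int(np.sum(np.sqrt(eigvals) > truncation)), 1)
    return ICVModel(
        mean=mean,
        covariance=np.diag(eigvals[:keep]),
        retained_dims=keep,
        basis=eigvecs[:, :keep],
        detrended=detrend,
        metadata={"n_years": series.n_years, "truncation_sd": truncation},
    )
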