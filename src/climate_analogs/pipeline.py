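"""Per-city × per-scenario analog mapping, classification, and summaries.

For each city and future scenario the pipeline evaluates sigma dissimilarity
between the city's expected future climate and every valid contemporary cell
of the analog pool, producing a similarity surface; the cell with the
smallest sigma is the best contemporary analog. Analog strength classifies
as representative (σ ≤ 2), poor (2 < σ ≤ 4), or novel (σ > 4). Ensembles
average climate variables across members before the statistic — sigma is
never averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalogError, DomainError
from .geodesy import GeodesicResult, circular_mean_deg, geodesic_distance_bearing
from .grids import ClimateGrid, SeasonalClimateVector, UrbanArea, city_pool_cell_count, ensemble_mean
from .sigma import SIGMA_CAP, mahalanobis_batch, sigma_from_distance
from .stations import ICVModel

#: Sigma thresholds: analogs at or below the first are representative of the
#: city's future climate; above the second the future climate is novel.
REPRESENTATIVE_SIGMA = 2.0
NOVEL_SIGMA = 4.0


def classify(sigma: float) -> str:
    """Analog class from sigma: representative (≤2σ), poor, or novel (>4σ).

    Boundary convention: exactly 2σ is still representative, exactly 4σ is
    poor (the novelty threshold is strict).
    """
    if sigma < 0 or not np.isfinite(sigma):
        raise ValueError(f"sigma must be finite and nonnegative, got {sigma}")
    if sigma <= REPRESENTATIVE_SIGMA:
        return "representative"
    if sigma <= NOVEL_SIGMA:
        return "poor"
    return "novel"


@dataclass
class SimilaritySurface:
    """Sigma dissimilarity of one city × scenario over the analog pool grid."""

    sigma: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    mask: np.ndarray
    city: str
    scenario: str
    dof: int
    saturated: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.sigma.shape


@dataclass(frozen=True)
class AnalogResult:
    """Best contemporary analog for one city × scenario."""

    city: str
    scenario: str
    best_lat: float
    best_lon: float
    min_sigma: float
    distance_km: float
    bearing_deg: float
    analog_class: str
    tie_count: int
    degenerate_bearing: bool = False
    saturated: bool = False


@dataclass(frozen=True)
class CohortSummary:
    """Cross-city summary for one scenario (or one region within it)."""

    scenario: str
    n: int
    mean_distance_km: float
    mean_bearing_deg: float
    frac_representative: float
    frac_novel: float
    n_bearing_excluded: int
    region: str | None = None


def similarity_surface(
    city_future: SeasonalClimateVector,
    pool: ClimateGrid,
    icv: ICVModel,
    city: str = "",
    scenario: str = "",
    cap: float = SIGMA_CAP,
) -> SimilaritySurface:
    """Sigma dissimilarity between a city's future climate and every pool cell."""
    vectors, flat_idx = pool.valid_vectors()
    if vectors.shape[0] == 0:
        raise DomainError("analog pool has no valid cells")
    diffs = city_future.values[None, :] - vectors
    d = mahalanobis_batch(diffs, icv)
    sig, _, _, sat = sigma_from_distance(d, icv.retained_dims, cap)
    sigma_grid = np.full(pool.shape, np.nan)
    sat_grid = np.zeros(pool.shape, dtype=bool)
    sigma_grid.ravel()[flat_idx] = sig
    sat_grid.ravel()[flat_idx] = sat
    return SimilaritySurface(
        sigma=sigma_grid,
        lat=pool.lat.copy(),
        lon=pool.lon.copy(),
        mask=pool.mask.copy(),
        city=city,
        scenario=scenario,
        dof=icv.retained_dims,
        saturated=sat_grid,
    )


def best_analog(surface: SimilaritySurface, city: UrbanArea) -> AnalogResult:
    """Locate the pool cell with minimum sigma and measure distance/bearing.

    Ties on the exact minimum are broken by row-major scan order of the
    stored surface (deterministic and auditable); the number of tied cells
    is recorded. Distance and initial bearing run from the city centroid to
    the winning cell center on a sphere.
    """
    flat = surface.sigma.ravel()
    valid = np.isfinite(flat)
    if not valid.any():
        raise DomainError(f"{surface.city or city.name}: all-masked similarity surface")
    min_sigma = np.nanmin(flat)
    ties = np.flatnonzero(valid & (flat == min_sigma))
    winner = int(ties[0])
    i, j = np.unravel_index(winner, surface.shape)
    best = (float(surface.lat[i]), float(surface.lon[j]))
    geo: GeodesicResult = geodesic_distance_bearing(city.centroid, best)
    saturated = bool(surface.saturated[i, j]) if surface.saturated is not None else False
    return AnalogResult(
        city=surface.city or city.name,
        scenario=surface.scenario,
        best_lat=best[0],
        best_lon=best[1],
        min_sigma=float(min_sigma),
        distance_km=geo.distance_km,
        bearing_deg=geo.bearing_deg,
        analog_class=classify(float(min_sigma)),
        tie_count=int(ties.size),
        degenerate_bearing=geo.degenerate,
        saturated=saturated,
    )


def run_scenarios(
    cities: Sequence[UrbanArea],
    pool: ClimateGrid,
    icv_per_city: Mapping[str, ICVModel],
    futures: Mapping[str, Mapping[str, SeasonalClimateVector]],
    ensemble: bool = False,
    groups: Mapping[str, str] | None = None,
    cap: float = SIGMA_CAP,
) -> tuple[list[AnalogResult], dict[str, str]]:
    """Best analogs for every city × scenario (or city × ensemble group).

    ``futures[city_name][scenario_id]`` is the city's future 12-vector under
    that scenario. With ``ensemble=True``, scenarios are grouped by
    ``groups`` (scenario_id → group label, e.g. an RCP; one group when
    omitted) and climate variables are averaged across members *before*
    sigma is computed — averaging sigma values is not reachable through this
    pipeline. Cities missing an ICV model or a future vector are
    quarantined: their failure is reported in the returned manifest and the
    remaining cities proceed. Results are ordered (city, scenario).
    """
    results: list[AnalogResult] = []
    failures: dict[str, str] = {}
    for city in cities:
        try:
            icv = icv_per_city.get(city.name)
            if icv is None:
                raise AnalogError(f"{city.name}: no ICV model")
            city_futures = futures.get(city.name)
            if not city_futures:
                raise AnalogError(f"{city.name}: no future climate vectors")
            if ensemble:
                by_group: dict[str, list[SeasonalClimateVector]] = {}
                for sid in sorted(city_futures):
                    g = groups.get(sid, "ensemble") if groups else "ensemble"
                    by_group.setdefault(g, []).append(city_futures[sid])
                tasks = [
                    (g, ensemble_mean(members)) for g, members in sorted(by_group.items())
                ]
            else:
                tasks = [(sid, city_futures[sid]) for sid in sorted(city_futures)]
            for sid, vec in tasks:
                surf = similarity_surface(
                    vec, pool, icv, city=city.name, scenario=sid, cap=cap
                )
                results.append(best_analog(surf, city))
        except AnalogError as exc:
            failures[city.name] = str(exc)
    return results, failures


def summarize(
    results: Sequence[AnalogResult],
    region_tags: Mapping[str, str] | None = None,
) -> list[CohortSummary]:
    """Cohort summaries per scenario (and per region when tags are given).

    Distances average arithmetically; bearings average as directions
    (circular mean of the resultant vector), with degenerate bearings from
    coincident city/analog points excluded and counted. Fractions report
    representative (≤2σ) and novel (>4σ) shares.
    """
    if not results:
        raise ValueError("no results to summarize")
    out: list[CohortSummary] = []
    by_scenario: dict[str, list[AnalogResult]] = {}
    for r in results:
        by_scenario.setdefault(r.scenario, []).append(r)
    for scenario in sorted(by_scenario):
        group = by_scenario[scenario]
        partitions: list[tuple[str | None, list[AnalogResult]]] = [(None, group)]
        if region_tags:
            by_region: dict[str, list[AnalogResult]] = {}
            for r in group:
                tag = region_tags.get(r.city)
                if tag is not None:
                    by_region.setdefault(tag, []).append(r)
            partitions += sorted(by_region.items())
        for region, members in partitions:
            bearings = np.array(
                [r.bearing_deg for r in members if not r.degenerate_bearing]
            )
            n_excluded = len(members) - bearings.size
            out.append(
                CohortSummary(
                    scenario=scenario,
                    region=region,
                    n=len(members),
                    mean_distance_km=float(np.mean([r.distance_km for r in members])),
                    mean_bearing_deg=circular_mean_deg(bearings) if bearings.size else float("nan"),
                    frac_representative=float(
                        np.mean([r.analog_class == "representative" for r in members])
                    ),
                    frac_novel=float(np.mean([r.analog_class == "novel" for r in members])),
                    n_bearing_excluded=n_excluded,
                )
            )
    return out


def filter_urban_areas(
    cities: Sequence[UrbanArea],
    min_area_km2: float = 50.0,
    station_check: Callable[[UrbanArea], bool] | None = None,
    heterogeneity_check: Callable[[UrbanArea], bool] | None = None,
    pool: ClimateGrid | None = None,
) -> tuple[list[UrbanArea], list[tuple[UrbanArea, str]]]:
    """Apply the urban-area inclusion filters, recording exclusion reasons.

    Cities must exceed ``min_area_km2`` (~>50 km², so the pixel sample inside
    the polygon is large enough), pass the station-availability check, and —
    when a pool grid or explicit check is supplied — intersect at least two
    distinct valid pool cells (a minimal proxy for the spatial climatic
    heterogeneity the statistic needs). Every exclusion carries a
    machine-readable reason: "area", "stations", or "heterogeneity".
    """
    kept: list[UrbanArea] = []
    excluded: list[tuple[UrbanArea, str]] = []
    for city in cities:
        if city.area_km2 <= min_area_km2:
            excluded.append((city, "area"))
            continue
        if station_check is not None and not station_check(city):
            excluded.append((city, "stations"))
            continue
        het_ok = True
        if heterogeneity_check is not None:
            het_ok = heterogeneity_check(city)
        elif pool is not None:
            het_ok = city_pool_cell_count(pool, city) >= 2
        if not het_ok:
            excluded.append((city, "heterogeneity"))
            continue
        kept.append(city)
    return kept, excluded


def results_to_dataframe(results: Sequence[AnalogResult]) -> pd.DataFrame:
    """One row per city × scenario with all analog-result fields."""
    return pd.DataFrame([r.__dict__ for r in results])
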