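"""Landscape application: site-index maps and assisted-migration optimisation.

Each grid point plays two roles: as a plantation site (with scenario
climate series) and as a candidate seed source (with its own 1961-1990
normals as the "local population" climate).  ``map_local_si`` projects the
local population under a scenario; ``select_optimal_population`` scans a
candidate set of provenance climates for the one expected to grow tallest
at age 50, quantifying the gain available from assisted migration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .curves import build_curve, site_index_at_50
from .gypsy import SpeciesParams
from .urf import UrfFit

__all__ = [
    "GridPoint",
    "SiMapRecord",
    "NO_CHANGE_SCENARIO",
    "map_local_si",
    "select_optimal_population",
    "sample_candidates",
    "apply_extrapolation_exclusion",
    "records_to_frame",
    "records_to_geojson",
]

log = logging.getLogger(__name__)

NO_CHANGE_SCENARIO = "NCC"

#: Sites whose optimal-population SI exceeds this (m) lie outside the
#: climate space spanned by the trials and are flagged as extrapolation.
DEFAULT_EXCLUSION_THRESHOLD = 25.0


@dataclass
class GridPoint:
    """One landscape location with its climates.

    ``scenarios`` maps a scenario label (e.g. "NCC", "SSP245") to the
    annual :class:`ClimateSeries` the plantation would experience there.
    ``prov_normals`` are the local 1961-1990 normals, i.e. the climate of
    the geographically local population.
    """

    point_id: str
    lon: float
    lat: float
    in_range: bool
    prov_normals: dict[str, float]
    scenarios: dict[str, ClimateSeries]


@dataclass
class SiMapRecord:
    point_id: str
    scenario: str
    si_local: float
    si_dif: float
    si_opt: float = np.nan
    si_imp: float = np.nan
    optimal_prov_climate: dict[str, float] | None = None
    excluded: bool = False


def _age50_height(point: GridPoint, prov_normals: dict[str, float],
                  urf: UrfFit, params: SpeciesParams, scenario: str,
                  plant_year: int, smooth: bool) -> float:
    curve = build_curve(params, urf, prov_normals,
                        point.scenarios[scenario], plant_year,
                        ages=50, smooth=smooth,
                        scenario_label=scenario)
    return site_index_at_50(curve)


def map_local_si(grid: list[GridPoint], urf: UrfFit, params: SpeciesParams,
                 scenario: str, plant_year: int,
                 smooth: bool = True) -> list[SiMapRecord]:
    """Age-50 site index of the local population at every in-range point.

    ``si_local`` is the assembled-curve height at age 50 with provenance
    climate equal to the point's own normals; ``si_dif`` is the change
    relative to the no-climate-change replay of those normals.  Points
    outside the species range are skipped (count logged).
    """
    records = []
    skipped = 0
    for point in grid:
        if not point.in_range:
            skipped += 1
            continue
        si_scen = _age50_height(point, point.prov_normals, urf, params,
                                scenario, plant_year, smooth)
        if scenario == NO_CHANGE_SCENARIO:
            si_base = si_scen
        else:
            si_base = _age50_height(point, point.prov_normals, urf, params,
                                    NO_CHANGE_SCENARIO, plant_year, smooth)
        records.append(SiMapRecord(point.point_id, scenario,
                                   si_local=si_scen,
                                   si_dif=si_scen - si_base))
    if skipped:
        log.info("skipped %d out-of-range grid points", skipped)
    return records


def sample_candidates(grid: list[GridPoint], n: int = 100,
                      seed: int = 0) -> list[dict[str, float]]:
    """Sample candidate provenance climates from in-range grid points.

    The natural range is represented by the in-range points; ``n`` of them
    are drawn uniformly without replacement (all of them if fewer exist)
    and their 1961-1990 normals become the candidate seed-source climates.
    """
    pool = [p for p in grid if p.in_range]
    rng = np.random.default_rng(seed)
    if len(pool) > n:
        idx = sorted(rng.choice(len(pool), size=n, replace=False))
        pool = [pool[i] for i in idx]
    return [dict(p.prov_normals) for p in pool]


def select_optimal_population(point: GridPoint,
                              candidates: list[dict[str, float]],
                              urf: UrfFit, params: SpeciesParams,
                              scenario: str, plant_year: int,
                              smooth: bool = True,
                              si_local: float | None = None):
    """Best seed source for one plantation point under one scenario.

    Evaluates the age-50 height of every candidate provenance climate at
    the point's scenario climate and returns ``(best_candidate, si_opt,
    si_imp)`` with ties broken toward the first candidate.  ``si_imp`` is
    the gain over the local population (non-negative whenever the local
    provenance is among the candidates).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    best, si_opt = None, -np.inf
    for cand in candidates:
        si = _age50_height(point, cand, urf, params, scenario,
                           plant_year, smooth)
        if si > si_opt:
            best, si_opt = cand, si
    if si_local is None:
        si_local = _age50_height(point, point.prov_normals, urf, params,
                                 scenario, plant_year, smooth)
    return best, si_opt, si_opt - si_local


def map_optimal_si(grid: list[GridPoint], urf: UrfFit, params: SpeciesParams,
                   scenario: str, plant_year: int,
                   candidates: list[dict[str, float]] | None = None,
                   n_candidates: int = 100, seed: int = 0,
                   smooth: bool = True,
                   threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
                   ) -> list[SiMapRecord]:
    """Local and optimal-population SI for every in-range point."""
    if candidates is None:
        candidates = sample_candidates(grid, n_candidates, seed)
    records = map_local_si(grid, urf, params, scenario, plant_year, smooth)
    by_id = {p.point_id: p for p in grid}
    for rec in records:
        point = by_id[rec.point_id]
        best, si_opt, si_imp = select_optimal_population(
            point, candidates, urf, params, scenario, plant_year,
            smooth, si_local=rec.si_local)
        rec.si_opt, rec.si_imp = si_opt, si_imp
        rec.optimal_prov_climate = best
    return apply_extrapolation_exclusion(records, threshold)


def apply_extrapolation_exclusion(records: list[SiMapRecord],
                                  threshold: float = DEFAULT_EXCLUSION_THRESHOLD,
                                  ) -> list[SiMapRecord]:
    """Flag records whose optimal SI strictly exceeds the threshold.

    Records are flagged, never deleted: an SI above the threshold signals
    climate extrapolation beyond the trial envelope, not a missing value.
    """
    for rec in records:
        rec.excluded = bool(np.isfinite(rec.si_opt)
                            and rec.si_opt > threshold)
    return records


def records_to_frame(records: list[SiMapRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({"point_id": r.point_id, "scenario": r.scenario,
                     "si_local": r.si_local, "si_dif": r.si_dif,
                     "si_opt": r.si_opt, "si_imp": r.si_imp,
                     "excluded": r.excluded})
    return pd.DataFrame(rows)


def records_to_geojson(records: list[SiMapRecord],
                       grid: list[GridPoint]) -> dict:
    """GeoJSON FeatureCollection mirroring the record columns."""
    by_id = {p.point_id: p for p in grid}
    features = []
    for r in records:
        p = by_id[r.point_id]
        props = {"point_id": r.point_id, "scenario": r.scenario,
                 "si_local": r.si_local, "si_dif": r.si_dif,
                 "si_opt": None if np.isnan(r.si_opt) else r.si_opt,
                 "si_imp": None if np.isnan(r.si_imp) else r.si_imp,
                 "excluded": r.excluded}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
            "properties": props,
        })
    return {"type": "FeatureCollection", "features": features}
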