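"""Synthetic provenance trials, climates and landscape grids with known truth.

Real provenance-trial measurements are not redistributable, so every other
module is exercised against data generated here from a known ground-truth
response function: multi-site, multi-population trials in randomized
complete blocks with row plots, tree-level lognormal noise, additive block
effects and Bernoulli health flags; climate normals laid out on linear
spatial gradients with annual series around them, optionally warming.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import (CLIMATE_VARIABLES, ClimateSeries, constant_series,
                      lifespan_average)
from .deploy import NO_CHANGE_SCENARIO, GridPoint
from .gypsy import SpeciesParams, evaluate_top_height, invert_site_index
from .urf import UrfFit, UrfSpec

__all__ = [
    "TruthConfig",
    "Landscape",
    "default_true_urf",
    "make_climate_landscape",
    "make_urf_dataset",
    "make_trial_dataset",
    "make_deployment_grid",
]

#: Typical boreal-plain normals used as field baselines, and the spatial
#: standard deviation of each variable across a regional landscape.
CLIMATE_BASES: dict[str, tuple[float, float]] = {
    "AHM": (24.0, 6.0), "CMD": (230.0, 70.0), "DD_0": (1600.0, 350.0),
    "DD5": (1350.0, 300.0), "Eref": (560.0, 60.0), "EMT": (-42.0, 4.0),
    "EXT": (32.0, 2.0), "FFP": (95.0, 18.0), "NFFD": (160.0, 25.0),
    "bFFP": (150.0, 10.0), "eFFP": (245.0, 10.0), "MAP": (480.0, 120.0),
    "MAT": (1.5, 2.0), "MCMT": (-12.0, 3.0), "MWMT": (15.5, 1.5),
    "MAR": (12.5, 1.0), "MSP": (300.0, 80.0), "CMI": (8.0, 5.0),
    "PAS": (140.0, 50.0), "RH": (62.0, 5.0), "SHM": (55.0, 15.0),
    "TD": (27.5, 3.0),
}

#: Interannual variability as a fraction of the spatial SD.
ANNUAL_SD_FRACTION = 0.4

UNHEALTHY_FLAGS = ("dead", "crooked", "browsed", "diseased")


def default_true_urf(prov_var: str = "MAT", site_var: str = "MAT",
                     ) -> UrfFit:
    """A plausible single-variable ground-truth response function.

    Log-quadratic in provenance and site mean annual temperature with a
    mild positive interaction: common-age heights near 10 m at the field
    baseline, an interior provenance optimum, and gentle curvature — the
    shape provenance trials in cold-temperate conifers typically show.
    """
    spec = UrfSpec((prov_var,), (site_var,))
    coefficients = {
        "Intercept": 2.3,
        f"{prov_var}.p": 0.05,
        f"{site_var}.s": 0.08,
        f"{prov_var}.p^2": -0.010,
        f"{site_var}.s^2": -0.012,
        f"{prov_var}.p:{site_var}.s": 0.004,
    }
    return UrfFit(spec, coefficients, r2=1.0, aic=np.nan, n_obs=0)


@dataclass
class TruthConfig:
    """Ground truth and design sizes for a synthetic trial series.

    Defaults emulate a realistic trial series: similar scale to published
    white-spruce series (17 sites, tens of populations), randomized
    complete blocks with five-tree row plots, 5% lognormal tree noise,
    modest additive block effects and a 10% unhealthy-tree rate.
    """

    true_urf: UrfFit
    species_params: SpeciesParams
    n_sites: int = 17
    n_populations: int = 40
    n_blocks: int = 6
    trees_per_plot: int = 5
    noise_sd_log: float = 0.05
    block_sd: float = 0.15
    unhealthy_rate: float = 0.10
    seed: int = 0
    measurement_ages: tuple[int, ...] | None = None

    def __post_init__(self):
        for name in ("n_sites", "n_populations", "n_blocks",
                     "trees_per_plot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("noise_sd_log", "block_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.unhealthy_rate <= 1:
            raise ValueError("unhealthy_rate must be in [0, 1]")

    def resolved_ages(self) -> tuple[int, ...]:
        """Measurement ages; default brackets the common age."""
        if self.measurement_ages is not None:
            return tuple(sorted(self.measurement_ages))
        ca = self.species_params.common_age
        return tuple(sorted({max(3, ca - 6), ca - 1, ca + 4}))


@dataclass
class Landscape:
    """Synthetic climate fields at a set of point locations."""

    coords: pd.DataFrame                  # point_id, lon, lat
    normals: pd.DataFrame                 # indexed by point_id, var columns
    series: dict[str, ClimateSeries]      # per point_id
    seed: int
    start_year: int


def make_climate_landscape(n_points: int, variable_names, seed: int,
                           lon_range=(-120.0, -110.0),
                           lat_range=(49.0, 60.0),
                           start_year: int = 1971, n_years: int = 90,
                           warming_trend: dict[str, float] | None = None,
                           correlated_copies: dict[str, tuple[str, float]]
                           | None = None) -> Landscape:
    """Correlated climate fields: linear spatial gradients plus noise.

    Each variable's normal is its baseline plus a gradient along a
    variable-specific direction across the lon/lat box plus site noise;
    annual series fluctuate around the normal and, when ``warming_trend``
    gives a per-year rate, the expected value in the ``k``-th year of the
    series exceeds the normal by ``rate * k``.

    ``correlated_copies`` maps a variable to ``(source_variable, noise_sd)``
    and overwrites its field with a noisy copy of the source — the hook
    used to build known correlation blocks for pruning tests.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    variable_names = list(variable_names)
    unknown = [v for v in variable_names if v not in CLIMATE_VARIABLES]
    if unknown:
        raise KeyError(f"unknown climate variable(s): {unknown}")
    warming_trend = warming_trend or {}
    rng = np.random.default_rng(seed)
    lon = rng.uniform(*lon_range, n_points)
    lat = rng.uniform(*lat_range, n_points)
    u = (lon - lon_range[0]) / (lon_range[1] - lon_range[0]) - 0.5
    v = (lat - lat_range[0]) / (lat_range[1] - lat_range[0]) - 0.5
    point_ids = [f"P{i:04d}" for i in range(n_points)]

    normals = {}
    for var in variable_names:
        base, spread = CLIMATE_BASES[var]
        theta = rng.uniform(0, 2 * np.pi)
        grad = 2.0 * spread * (np.cos(theta) * u + np.sin(theta) * v)
        noise = rng.normal(0.0, 0.35 * spread, n_points)
        normals[var] = base + grad + noise
    for var, (src, sd) in (correlated_copies or {}).items():
        if var not in normals or src not in normals:
            raise KeyError(f"correlated copy {var!r} <- {src!r} not in fields")
        normals[var] = normals[src] + rng.normal(0.0, sd, n_points)
    normals_df = pd.DataFrame(normals, index=pd.Index(point_ids,
                                                      name="point_id"))

    years = np.arange(start_year, start_year + n_years)
    k = np.arange(1, n_years + 1)
    series = {}
    for i, pid in enumerate(point_ids):
        annual = {}
        for var in variable_names:
            _, spread = CLIMATE_BASES[var]
            trend = warming_trend.get(var, 0.0) * k
            noise = rng.normal(0.0, ANNUAL_SD_FRACTION * spread, n_years)
            annual[var] = normals_df.iloc[i][var] + trend + noise
        series[pid] = ClimateSeries(pid, pd.DataFrame(annual, index=years),
                                    normals_df.iloc[i].to_dict())
    return Landscape(pd.DataFrame({"point_id": point_ids,
                                   "lon": lon, "lat": lat}),
                     normals_df, series, seed, start_year)


def _climate_frames(truth: TruthConfig, landscape: Landscape):
    """Split landscape points into sites and populations; build covariates."""
    urf = truth.true_urf
    needed = truth.n_sites + truth.n_populations
    if len(landscape.normals) < needed:
        raise ValueError(f"landscape has {len(landscape.normals)} points; "
                         f"need {needed} for sites + populations")
    ids = list(landscape.normals.index)
    site_ids, pop_ids = ids[:truth.n_sites], ids[truth.n_sites:needed]
    prov = landscape.normals.loc[pop_ids, list(urf.spec.prov_vars)]
    ca = truth.species_params.common_age
    site = pd.DataFrame(
        {v: [lifespan_average(landscape.series[s], v,
                              landscape.start_year, ca) for s in site_ids]
         for v in urf.spec.site_vars},
        index=pd.Index(site_ids, name="point_id"))
    return site_ids, pop_ids, prov, site


def _truth_table(truth: TruthConfig, prov: pd.DataFrame,
                 site: pd.DataFrame) -> pd.DataFrame:
    """Noiseless common-age heights for every population x site."""
    urf, params = truth.true_urf, truth.species_params
    rows = []
    for s in site.index:
        for p in prov.index:
            h = urf.predict(prov.loc[p].to_dict(), site.loc[s].to_dict())
            rows.append({"site_id": s, "population_id": p,
                         "totage": params.common_age, "top_height": h})
    return pd.DataFrame(rows)


def make_urf_dataset(true_urf: UrfFit, n_sites: int, n_populations: int,
                     noise_sd_log: float, seed: int,
                     extra_prov_vars=(), extra_site_vars=(),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population x site fit table drawn directly from a true URF.

    Generates independent provenance and site climate draws from the field
    baselines, computes true common-age heights and multiplies lognormal
    noise.  ``extra_*_vars`` add distractor climate columns that do not
    enter the truth, for selection-consistency experiments.  Returns
    ``(fit_table, truth_table)`` where the fit table has the ``<var>.p`` /
    ``<var>.s`` columns that :func:`climtop.urf.fit_urf` consumes.
    """
    rng = np.random.default_rng(seed)
    pvars = list(dict.fromkeys(list(true_urf.spec.prov_vars)
                               + list(extra_prov_vars)))
    svars = list(dict.fromkeys(list(true_urf.spec.site_vars)
                               + list(extra_site_vars)))
    pop_ids = [f"J{i:03d}" for i in range(n_populations)]
    site_ids = [f"T{i:03d}" for i in range(n_sites)]

    def draws(varlist, n):
        return pd.DataFrame({v: rng.normal(*CLIMATE_BASES[v], n)
                             for v in varlist})

    prov = draws(pvars, n_populations).set_index(pd.Index(pop_ids))
    site = draws(svars, n_sites).set_index(pd.Index(site_ids))
    rows = []
    for s in site_ids:
        for p in pop_ids:
            h = true_urf.predict(
                prov.loc[p, list(true_urf.spec.prov_vars)].to_dict(),
                site.loc[s, list(true_urf.spec.site_vars)].to_dict())
            rows.append({"site_id": s, "population_id": p, "true_height": h})
    table = pd.DataFrame(rows)
    noise = np.exp(rng.normal(0.0, noise_sd_log, len(table)))
    table["top_height"] = table["true_height"] * noise
    fit_table = table[["site_id", "population_id", "top_height"]].copy()
    fit_table = fit_table.join(prov.add_suffix(".p"), on="population_id")
    fit_table = fit_table.join(site.add_suffix(".s"), on="site_id")
    truth = (table[["site_id", "population_id", "true_height"]]
             .rename(columns={"true_height": "top_height"}))
    return fit_table, truth


def make_trial_dataset(truth: TruthConfig, landscape: Landscape,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tree-level trial table plus its noiseless ground truth.

    The first ``n_sites`` landscape points become test sites and the next
    ``n_populations`` become populations.  Expected common-age heights come
    from the true URF; per-age expectations are back-computed through the
    species curve (invert to SI, evaluate at each measurement age).  Tree
    heights multiply lognormal noise onto the expectation and add the
    block's shift (zero-sum within site); health flags are Bernoulli.
    """
    params = truth.species_params
    rng = np.random.default_rng(truth.seed)
    site_ids, pop_ids, prov, site = _climate_frames(truth, landscape)
    truth_df = _truth_table(truth, prov, site)
    ages = truth.resolved_ages()

    si = {}
    for _, row in truth_df.iterrows():
        si[(row["site_id"], row["population_id"])] = invert_site_index(
            params, row["top_height"], params.common_age)

    rows = []
    for s in site_ids:
        shifts = rng.normal(0.0, truth.block_sd, truth.n_blocks)
        shifts -= shifts.mean()  # block effects are contrasts within a site
        for age in ages:
            for p in pop_ids:
                mean_h = evaluate_top_height(params, si[(s, p)], age)
                for b in range(truth.n_blocks):
                    noise = np.exp(rng.normal(0.0, truth.noise_sd_log,
                                              truth.trees_per_plot))
                    heights = np.maximum(mean_h * noise + shifts[b], 0.05)
                    sick = rng.random(truth.trees_per_plot) < truth.unhealthy_rate
                    flags = np.where(
                        sick, rng.choice(UNHEALTHY_FLAGS,
                                         truth.trees_per_plot), "healthy")
                    for t in range(truth.trees_per_plot):
                        rows.append({
                            "site_id": s, "population_id": p,
                            "block_id": f"B{b}", "tree_id": f"{p}-{b}-{t}",
                            "totage": age,
                            "height_m": float(heights[t]),
                            "health_flag": str(flags[t]),
                        })
    return pd.DataFrame(rows), truth_df


def make_deployment_grid(n_points: int, urf: UrfFit, seed: int,
                         scenarios: dict[str, dict[str, float]] | None = None,
                         plant_year: int = 2006, n_years: int = 60,
                         in_range_fraction: float = 1.0,
                         ) -> list[GridPoint]:
    """Landscape grid for SI mapping, with per-scenario climate series.

    ``scenarios`` maps a label to a per-variable warming trend (units/yr);
    the no-change scenario replays each point's normals as a constant
    series and is always present.  ``in_range_fraction`` of the points are
    marked inside the species range (the rest carry climate but are
    skipped by the mapping routines).
    """
    variables = sorted(set(urf.spec.prov_vars) | set(urf.spec.site_vars))
    scenarios = scenarios or {}
    land = make_climate_landscape(n_points, variables, seed,
                                  start_year=plant_year, n_years=n_years)
    rng = np.random.default_rng(seed + 1)
    in_range = rng.random(n_points) < in_range_fraction
    points = []
    for i, pid in enumerate(land.normals.index):
        normals = land.normals.loc[pid].to_dict()
        scen = {NO_CHANGE_SCENARIO: constant_series(pid, normals,
                                                    plant_year, n_years)}
        for label, trend in scenarios.items():
            trended = make_climate_landscape(
                1, variables, seed + 1000 + i, start_year=plant_year,
                n_years=n_years, warming_trend=trend)
            # re-centre the independent draw on this point's normals
            shifted = trended.series[trended.normals.index[0]]
            delta = {v: normals[v] - trended.normals.iloc[0][v]
                     for v in variables}
            annual = shifted.annual.add(pd.Series(delta), axis=1)
            scen[label] = ClimateSeries(pid, annual, normals)
        points.append(GridPoint(pid, float(land.coords.loc[i, "lon"]),
                                float(land.coords.loc[i, "lat"]),
                                bool(in_range[i]), normals, scen))
    return points
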