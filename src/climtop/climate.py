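"""Climate-variable registry, correlation pruning and site-climate summaries.

Climate enters the response functions in two roles: provenance climate
(1961-1990 normals — the climate a population is adapted to) and site
climate (annual values averaged from the planting year to the age of
interest — the climate a plantation has actually experienced).  This
module manages both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLIMATE_VARIABLES",
    "VARIABLE_ORDER",
    "ClimateSeries",
    "constant_series",
    "prune_correlated",
    "lifespan_average",
    "smooth_log_regression",
]

#: Registry of annual climate variables: abbreviation -> (description, unit).
#: Order is significant: it is the canonical ordering used for deterministic
#: tie-breaking and output ordering.  Degree-day variables relative to 18 °C
#: (heating/cooling degree-days) carry no direct biological interpretation
#: and are deliberately absent.
CLIMATE_VARIABLES: dict[str, tuple[str, str]] = {
    "AHM": ("annual heat-moisture index", "degC/mm"),
    "CMD": ("Hargreaves climatic moisture deficit", "mm"),
    "DD_0": ("degree-days below 0 degC", "degC days"),
    "DD5": ("degree-days above 5 degC", "degC days"),
    "Eref": ("Hargreaves reference evaporation", "mm"),
    "EMT": ("extreme minimum temperature over 30 years", "degC"),
    "EXT": ("extreme maximum temperature over 30 years", "degC"),
    "FFP": ("frost-free period", "days"),
    "NFFD": ("number of frost-free days", "days"),
    "bFFP": ("day of year on which FFP begins", "day"),
    "eFFP": ("day of year on which FFP ends", "day"),
    "MAP": ("mean annual precipitation", "mm"),
    "MAT": ("mean annual temperature", "degC"),
    "MCMT": ("mean coldest month temperature", "degC"),
    "MWMT": ("mean warmest month temperature", "degC"),
    "MAR": ("mean annual solar radiation", "MJ m-2 d-1"),
    "MSP": ("mean summer precipitation", "mm"),
    "CMI": ("Hogg's climate moisture index", "mm"),
    "PAS": ("precipitation as snow", "mm"),
    "RH": ("mean annual relative humidity", "%"),
    "SHM": ("summer heat-moisture index", "degC/mm"),
    "TD": ("continentality (MWMT - MCMT)", "degC"),
}

VARIABLE_ORDER = tuple(CLIMATE_VARIABLES)


def _check_variables(names) -> None:
    unknown = [n for n in names if n not in CLIMATE_VARIABLES]
    if unknown:
        raise KeyError(f"unknown climate variable(s): {unknown}; "
                       f"expected abbreviations from the registry")


@dataclass
class ClimateSeries:
    """Annual climate values plus normals at one location.

    ``annual`` is a DataFrame indexed by calendar year with one column per
    climate variable; ``normals`` maps variable -> value for the named
    normal period.  Years must be contiguous and variables must be
    registry abbreviations.
    """

    location_id: str
    annual: pd.DataFrame
    normals: dict[str, float] = field(default_factory=dict)
    normal_period: str = "1961-1990"

    def __post_init__(self):
        _check_variables(self.annual.columns)
        _check_variables(self.normals)
        years = np.asarray(self.annual.index, dtype=int)
        if len(years) and not np.array_equal(years,
                                             np.arange(years[0],
                                                       years[0] + len(years))):
            raise ValueError(
                f"years must be contiguous at {self.location_id!r}")
        self.annual = self.annual.sort_index()

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.annual.index, dtype=int)


def constant_series(location_id: str, normals: dict[str, float],
                    start_year: int, n_years: int,
                    normal_period: str = "1961-1990") -> ClimateSeries:
    """Replay a climate normal as a constant annual series.

    This is the "no climate change" scenario: every year of the plantation's
    life experiences the normal-period climate.
    """
    _check_variables(normals)
    years = np.arange(start_year, start_year + n_years)
    annual = pd.DataFrame({v: np.full(n_years, val)
                           for v, val in normals.items()}, index=years)
    return ClimateSeries(location_id, annual, dict(normals), normal_period)


def prune_correlated(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Drop one variable from every highly correlated pair.

    ``table`` holds locations in rows and registry climate variables in
    columns.  Pearson ``|r|`` is computed on the table; while any pair
    exceeds ``threshold``, the variable involved in the largest number of
    above-threshold pairs is removed (ties broken toward the variable
    appearing later in the registry ordering).  Returns the retained names
    in registry order.

    Raises
    ------
    ValueError
        If fewer than 3 locations are given or a column is constant.
    """
    _check_variables(table.columns)
    if len(table) < 3:
        raise ValueError("need at least 3 locations to estimate correlations")
    stds = table.std(ddof=0)
    constant = [c for c in table.columns if stds[c] == 0]
    if constant:
        raise ValueError(f"constant column(s): {constant}")
    # order columns canonically so the tie-break is well defined
    cols = [v for v in VARIABLE_ORDER if v in table.columns]
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    keep = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(keep, keep)]
        degrees = (sub > threshold).sum(axis=1)
        if degrees.max() == 0:
            break
        worst = degrees.max()
        # ties -> later in registry order: scan from the end
        drop_pos = max(i for i, d in enumerate(degrees) if d == worst)
        keep.pop(drop_pos)
    return [cols[i] for i in keep]


def lifespan_average(series: ClimateSeries, variable: str,
                     plant_year: int, age: int) -> float:
    """Mean annual value over the plantation's life so far.

    Averages calendar years ``plant_year .. plant_year + age - 1`` (``age``
    values): the climate the stand has experienced from planting to age
    ``age``.

    Raises
    ------
    ValueError
        If any required year is missing (the gaps are listed).
    """
    _check_variables([variable])
    wanted = np.arange(plant_year, plant_year + age)
    have = set(series.years)
    gaps = [int(y) for y in wanted if y not in have]
    if gaps:
        raise ValueError(f"series {series.location_id!r} missing years {gaps} "
                         f"for variable {variable!r}")
    return float(series.annual.loc[wanted, variable].mean())


def smooth_log_regression(values_by_age: dict[int, float]) -> dict[int, float]:
    """Smooth an age-indexed climate path with a log-age regression.

    Fits ``v(i) = c0 + c1 * ln(i)`` by ordinary least squares over the
    supplied ages and returns the fitted values at the same ages.  Used to
    strip inter-annual noise from lifespan-averaged climates so projected
    top-height curves are smooth.

    Raises
    ------
    ValueError
        If fewer than 3 ages are supplied.
    """
    ages = np.array(sorted(values_by_age), dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 ages for the log regression")
    y = np.array([values_by_age[int(a)] for a in ages])
    X = np.column_stack([np.ones_like(ages), np.log(ages)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return {int(a): float(v) for a, v in zip(ages, fitted)}
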