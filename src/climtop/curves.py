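"""Assembly of population-specific climate-sensitive top-height curves.

The merging algorithm couples a fitted response function to the static
site-index curves, age by age:

1. For each age ``i``, average the site climate from the planting year to
   age ``i`` (optionally smoothed with a log-age regression) and predict
   the common-age top height for the chosen provenance under that climate.
2. Invert the species' height equation at the common age to get the site
   index ``SI_i`` implied by that prediction.
3. ``SI_i`` defines a climate-non-sensitive curve for age ``i``.
4. Chain the curves: keep the age-1 height from the ``SI_1`` curve, then
   add the age-``i`` annual increment of the ``SI_i`` curve to the running
   height.

Under a constant climate every ``SI_i`` is identical and the chained curve
telescopes back to the static curve exactly — the defining consistency
property of the construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateSeries, lifespan_average, smooth_log_regression
from .gypsy import (InversionError, SpeciesParams, annual_increment,
                    evaluate_top_height, invert_site_index)
from .urf import UrfFit

__all__ = ["ClimSensCurve", "build_curve", "site_index_at_50"]

log = logging.getLogger(__name__)


@dataclass
class ClimSensCurve:
    """A climate-sensitive top-height trajectory for one provenance-site pair."""

    species_code: str
    provenance_id: str
    site_id: str
    scenario_label: str
    ages: np.ndarray           # 1..A
    heights: np.ndarray        # m, non-decreasing
    si_profile: np.ndarray     # SI_i solved at each age, m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "si_i": self.si_profile,
                             "height_m": self.heights})

    @property
    def si50(self) -> float:
        return site_index_at_50(self)


def site_index_at_50(curve: ClimSensCurve) -> float:
    """Height at total age 50 — the site index of the assembled curve."""
    if curve.ages[-1] < 50:
        raise ValueError(f"curve ends at age {curve.ages[-1]}; need >= 50")
    return float(curve.heights[curve.ages == 50][0])


def build_curve(params: SpeciesParams, urf: UrfFit,
                prov_normals: dict[str, float],
                site_series: ClimateSeries, plant_year: int,
                ages: int = 80, smooth: bool = False,
                provenance_id: str = "prov", scenario_label: str = "",
                ) -> ClimSensCurve:
    """Assemble the climate-sensitive curve for one provenance at one site.

    ``prov_normals`` holds the provenance's 1961-1990 normals for the
    response function's provenance variables; ``site_series`` must cover
    calendar years ``plant_year .. plant_year + ages - 1`` for its site
    variables.  ``smooth=True`` replaces each site variable's
    lifespan-average path by its log-age regression fit (recommended for
    projection runs, where inter-annual noise would otherwise ripple
    through the curve).

    Negative annual increments, which can occur when the solved site-index
    path collapses sharply, are floored at zero with a logged warning so
    that cumulative height never decreases.
    """
    A = int(ages)
    age_axis = np.arange(1, A + 1)
    site_vars = urf.spec.site_vars
    # lifespan-average path per site variable, optionally smoothed
    paths: dict[str, dict[int, float]] = {}
    for v in site_vars:
        path = {int(i): lifespan_average(site_series, v, plant_year, int(i))
                for i in age_axis}
        if smooth:
            path = smooth_log_regression(path)
        paths[v] = path

    si_profile = np.empty(A)
    for i in age_axis:
        site_vals = {v: paths[v][int(i)] for v in site_vars}
        ht_common = urf.predict(prov_normals, site_vals)
        try:
            si_profile[i - 1] = invert_site_index(params, ht_common,
                                                  params.common_age)
        except InversionError as exc:
            raise InversionError(
                f"age {i}: predicted common-age height {ht_common:g} m "
                f"not invertible ({exc})") from exc

    heights = np.empty(A)
    heights[0] = evaluate_top_height(params, si_profile[0], 1)
    for i in range(2, A + 1):
        inc = annual_increment(params, si_profile[i - 1], i)
        if inc < 0:
            log.warning("negative increment %.3g m at age %d floored to 0",
                        inc, i)
            inc = 0.0
        heights[i - 1] = heights[i - 2] + inc
    return ClimSensCurve(params.species_code, str(provenance_id),
                         site_series.location_id, scenario_label,
                         age_axis, heights, si_profile)
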