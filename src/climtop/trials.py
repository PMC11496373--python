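"""Provenance-trial preparation: from tree records to common-age top heights.

Trial tables are pandas DataFrames with columns ``site_id, population_id,
block_id, tree_id, totage, height_m, health_flag``.  The pipeline keeps
healthy trees only, estimates block-adjusted population mean heights per
site (population mean height stands in for top height, since competing
vegetation is controlled on trial sites), and converts each mean to the
species' common age through the site-index curve (invert to SI at the
measured age, evaluate at the common age).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .gypsy import SpeciesParams, evaluate_top_height, invert_site_index

__all__ = [
    "HEALTH_FLAGS",
    "TRIAL_COLUMNS",
    "filter_trees",
    "select_nearest_age",
    "estimate_population_heights",
    "convert_to_common_age",
    "population_common_age_heights",
    "read_trials_csv",
]

log = logging.getLogger(__name__)

HEALTH_FLAGS = ("healthy", "dead", "crooked", "browsed", "diseased")
TRIAL_COLUMNS = ("site_id", "population_id", "block_id", "tree_id",
                 "totage", "height_m", "health_flag")


def read_trials_csv(path) -> pd.DataFrame:
    """Read a trial CSV and validate its column contract."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    bad = set(df["health_flag"]) - set(HEALTH_FLAGS)
    if bad:
        raise ValueError(f"unknown health_flag values {sorted(bad)}")
    return df


def filter_trees(observations: pd.DataFrame) -> pd.DataFrame:
    """Keep healthy trees only; row order is preserved.

    Trees flagged dead, crooked, browsed or diseased do not express their
    site/genetic growth potential and are excluded before any averaging.
    """
    return observations[observations["health_flag"] == "healthy"]


def select_nearest_age(available_ages, common_age: int) -> int:
    """The measurement age closest to the common age; ties go to the older.

    Later measurements integrate more growth signal, hence the tie rule.
    """
    ages = list(available_ages)
    if not ages:
        raise ValueError("no measurement ages available")
    return max(sorted(ages), key=lambda a: (-abs(a - common_age), a))


def estimate_population_heights(observations: pd.DataFrame,
                                age: int, site_id) -> pd.DataFrame:
    """Block-adjusted population mean heights at one site and age.

    Fits a linear mixed model with population as a fixed effect (cell-mean
    coding, so each coefficient is an adjusted population mean) and block
    as a random intercept.  When the block variance component is estimated
    at zero the adjusted means coincide with raw population means.  A
    singular or non-convergent fit falls back to a fixed-effect block
    adjustment (population + block OLS, block effects averaged out).

    Returns a DataFrame with columns ``site_id, population_id, totage,
    top_height, n_trees``.
    """
    df = observations[(observations["site_id"] == site_id)
                      & (observations["totage"] == age)]
    if df.empty:
        raise ValueError(f"no observations for site {site_id!r} at age {age}")
    n_blocks = df["block_id"].nunique()
    if n_blocks < 2:
        raise ValueError(
            f"site {site_id!r} age {age}: need >= 2 blocks, have {n_blocks}")
    df = df.copy()
    df["population_id"] = df["population_id"].astype(str)
    df["block_id"] = df["block_id"].astype(str)

    means = _mixed_model_means(df, site_id, age)
    counts = df.groupby("population_id", sort=True)["height_m"].size()
    pops = sorted(means)
    return pd.DataFrame({
        "site_id": site_id,
        "population_id": pops,
        "totage": age,
        "top_height": [means[p] for p in pops],
        "n_trees": [int(counts[p]) for p in pops],
    })


def _mixed_model_means(df: pd.DataFrame, site_id, age) -> dict[str, float]:
    raw = df.groupby("population_id")["height_m"].mean()
    spread = max(float(df["height_m"].std(ddof=0)), 1e-9)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("height_m ~ 0 + C(population_id)", df,
                                groups=df["block_id"])
            fit = model.fit(reml=True)
        if not np.all(np.isfinite(fit.fe_params)):
            raise np.linalg.LinAlgError("non-finite fixed effects")
        means = {}
        for name, val in fit.fe_params.items():
            pop = name.split("[")[1].rstrip("]")
            means[pop] = float(val)
        # a genuine block adjustment cannot move a mean beyond the data
        # spread; larger excursions indicate a degenerate REML solution
        if any(abs(means[p] - raw[p]) > 3 * spread for p in means):
            raise np.linalg.LinAlgError("implausible adjusted means")
        return means
    except (np.linalg.LinAlgError, ValueError) as exc:
        log.info("site %r age %s: mixed model singular (%s); "
                 "falling back to fixed-effect block adjustment",
                 site_id, age, exc)
        return _fixed_effect_means(df)


def _fixed_effect_means(df: pd.DataFrame) -> dict[str, float]:
    """OLS population + block fit; block effects averaged out per population."""
    fit = smf.ols("height_m ~ C(population_id) + C(block_id)", df).fit()
    blocks = sorted(df["block_id"].unique())
    means = {}
    for pop in sorted(df["population_id"].unique()):
        grid = pd.DataFrame({"population_id": pop, "block_id": blocks})
        means[pop] = float(fit.predict(grid).mean())
    return means


def convert_to_common_age(params: SpeciesParams, height: float,
                          measured_age: int) -> float:
    """Project a height measured at one age to the species' common age.

    The height is inverted to a site index at the measured age, then the
    curve with that index is evaluated at the common age.  A height already
    at the common age is returned unchanged.
    """
    if measured_age == params.common_age:
        return float(height)
    si = invert_site_index(params, height, measured_age)
    return evaluate_top_height(params, si, params.common_age)


def population_common_age_heights(observations: pd.DataFrame,
                                  params: SpeciesParams) -> pd.DataFrame:
    """Full preparation pipeline over all sites of a trial table.

    Per site: drop unhealthy trees, pick the measurement age nearest the
    common age, estimate block-adjusted population means, and convert them
    to the common age.  Returns one row per population x site with columns
    ``site_id, population_id, totage, top_height, n_trees, measured_age``.
    """
    healthy = filter_trees(observations)
    out = []
    for site_id in sorted(healthy["site_id"].unique()):
        site_df = healthy[healthy["site_id"] == site_id]
        age = select_nearest_age(site_df["totage"].unique(),
                                 params.common_age)
        table = estimate_population_heights(site_df, age, site_id)
        table["measured_age"] = age
        table["top_height"] = [
            convert_to_common_age(params, h, age)
            for h in table["top_height"]
        ]
        table["totage"] = params.common_age
        out.append(table)
    return pd.concat(out, ignore_index=True)
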