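"""Universal Response Functions: enumeration, fitting and selection.

A Universal Response Function (URF) predicts common-age top height of a
population from its provenance climate (long-term genetic effect), the
test-site climate (environmental effect) and their interaction:

    HT = exp(a0 + sum_j a_j x_j + sum_t a_t x_t
             + sum_j q_j x_j^2 + sum_t q_t x_t^2
             + sum_{j,t} c_jt x_j x_t) + eps

with x_j provenance and x_t site climate variables (one to three of each).
The exponential-quadratic form gives a response surface with an interior
optimum in climate space, which is what makes seed-source optimisation
well posed.

Model search is exhaustive: every subset of one to three provenance and
one to three site variables is a candidate, grouped into nine categories
by the pair of subset sizes.  Screening fits are ordinary least squares on
the log scale (deterministic and fast enough for hundreds of thousands of
candidates); the best-R2 candidate per category goes to k-fold
cross-validation, and the candidate with the lowest RMSEP wins.  An
optional Gauss-Newton refinement re-estimates the winner on the original
height scale, matching the additive-error form above.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CollinearTermsError",
    "UrfSpec",
    "UrfFit",
    "count_candidates",
    "enumerate_specs",
    "build_terms",
    "make_fit_table",
    "fit_urf",
    "prediction_efficiency",
    "rmsep",
    "select_urf",
]

DEFAULT_CV_SEED = 20240513


class CollinearTermsError(ValueError):
    """The design matrix for a candidate is rank deficient."""


@dataclass(frozen=True)
class UrfSpec:
    """A candidate model: which climate variables enter on each side."""

    prov_vars: tuple[str, ...]
    site_vars: tuple[str, ...]
    include_intercept: bool = True

    def __post_init__(self):
        for side, vs in (("prov", self.prov_vars), ("site", self.site_vars)):
            if not 1 <= len(vs) <= 3:
                raise ValueError(f"{side}_vars must have 1-3 entries: {vs}")
            if len(set(vs)) != len(vs):
                raise ValueError(f"duplicate {side} variables: {vs}")

    @property
    def category(self) -> tuple[int, int]:
        """(number of provenance variables, number of site variables)."""
        return (len(self.prov_vars), len(self.site_vars))


def count_candidates(n_prov_vars: int, n_site_vars: int,
                     max_per_side: int = 3) -> int:
    """Number of candidate models given pool sizes on each side."""
    per = lambda n: sum(comb(n, k) for k in range(1, max_per_side + 1))
    return per(n_prov_vars) * per(n_site_vars)


def enumerate_specs(prov_pool, site_pool, max_per_side: int = 3,
                    include_intercept: bool = True):
    """Yield every candidate spec in deterministic order.

    Categories are visited in increasing (prov size, site size) order and,
    within a category, subsets follow lexicographic order over the pools as
    given.  The stream length equals :func:`count_candidates`.
    """
    prov_pool = list(prov_pool)
    site_pool = list(site_pool)
    for p in range(1, min(max_per_side, len(prov_pool)) + 1):
        for s in range(1, min(max_per_side, len(site_pool)) + 1):
            for pv in itertools.combinations(prov_pool, p):
                for sv in itertools.combinations(site_pool, s):
                    yield UrfSpec(pv, sv, include_intercept)


def build_terms(spec: UrfSpec) -> list[str]:
    """Ordered regression terms for a spec.

    Intercept (optional), linear provenance, linear site, quadratic
    provenance, quadratic site, then every provenance x site cross term.
    No provenance x provenance or site x site interactions — the surface is
    quadratic in each climate axis with genotype-by-environment curvature
    only through the cross terms.
    """
    terms = []
    if spec.include_intercept:
        terms.append("Intercept")
    terms += [f"{v}.p" for v in spec.prov_vars]
    terms += [f"{v}.s" for v in spec.site_vars]
    terms += [f"{v}.p^2" for v in spec.prov_vars]
    terms += [f"{v}.s^2" for v in spec.site_vars]
    terms += [f"{p}.p:{s}.s" for p in spec.prov_vars for s in spec.site_vars]
    return terms


def _term_columns(terms: list[str], get) -> list:
    """Evaluate each term via ``get(column_name)`` -> scalar or array."""
    cols = []
    for t in terms:
        if t == "Intercept":
            cols.append(1.0)
        elif t.endswith("^2"):
            v = get(t[:-2])
            cols.append(v * v)
        elif ":" in t:
            a, b = t.split(":")
            cols.append(get(a) * get(b))
        else:
            cols.append(get(t))
    return cols


def _design_matrix(spec: UrfSpec, data: pd.DataFrame) -> np.ndarray:
    terms = build_terms(spec)
    n = len(data)
    get = lambda c: data[c].to_numpy(dtype=float)
    cols = [np.full(n, c) if np.isscalar(c) else c
            for c in _term_columns(terms, get)]
    return np.column_stack(cols)


@dataclass
class UrfFit:
    """A fitted URF with its fit and cross-validation statistics.

    ``coefficients`` maps term name to value.  ``r2`` is computed on the
    original height scale from back-transformed predictions; ``aic`` comes
    from the Gaussian log-scale likelihood of the screening fit.  ``ef_cv``
    and ``rmsep_cv`` are filled by :func:`select_urf`.
    """

    spec: UrfSpec
    coefficients: dict[str, float]
    r2: float
    aic: float
    n_obs: int
    ef_cv: float = math.nan
    rmsep_cv: float = math.nan
    refined: bool = False

    def predict(self, prov_values: dict[str, float],
                site_values: dict[str, float]) -> float:
        """Predicted common-age top height (m) for one climate pair."""
        def get(col):
            var, side = col.rsplit(".", 1)
            src = prov_values if side == "p" else site_values
            return float(src[var])
        terms = list(self.coefficients)
        vals = _term_columns(terms, get)
        z = sum(self.coefficients[t] * v for t, v in zip(terms, vals))
        return math.exp(z)

    def predict_table(self, data: pd.DataFrame) -> np.ndarray:
        """Vectorised prediction on a fit table (``<var>.p``/``<var>.s`` columns)."""
        X = _design_matrix(self.spec, data)
        beta = np.array([self.coefficients[t] for t in build_terms(self.spec)])
        return np.exp(X @ beta)

    # -- serialisation ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": {"prov_vars": list(self.spec.prov_vars),
                     "site_vars": list(self.spec.site_vars),
                     "include_intercept": self.spec.include_intercept},
            "coefficients": self.coefficients,
            "r2": self.r2, "aic": self.aic, "n_obs": self.n_obs,
            "ef_cv": self.ef_cv, "rmsep_cv": self.rmsep_cv,
            "refined": self.refined,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UrfFit":
        spec = UrfSpec(tuple(d["spec"]["prov_vars"]),
                       tuple(d["spec"]["site_vars"]),
                       d["spec"].get("include_intercept", True))
        return cls(spec, dict(d["coefficients"]), d["r2"], d["aic"],
                   d["n_obs"], d.get("ef_cv", math.nan),
                   d.get("rmsep_cv", math.nan), d.get("refined", False))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "UrfFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_fit_table(heights: pd.DataFrame, prov_normals: pd.DataFrame,
                   site_climates: pd.DataFrame) -> pd.DataFrame:
    """Join common-age heights to provenance and site climate.

    ``heights`` needs columns ``site_id, population_id, top_height``;
    ``prov_normals`` is indexed by population_id and ``site_climates`` by
    site_id, each with climate-variable columns.  Climate columns are
    suffixed ``.p`` (provenance) and ``.s`` (site) in the result.
    """
    out = heights[["site_id", "population_id", "top_height"]].copy()
    p = prov_normals.add_suffix(".p")
    s = site_climates.add_suffix(".s")
    out = out.join(p, on="population_id").join(s, on="site_id")
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing climate values after join in {bad}")
    return out


def fit_urf(spec: UrfSpec, data: pd.DataFrame, refine: bool = False) -> UrfFit:
    """Fit one candidate URF to a fit table.

    The screening fit is OLS of ``ln(top_height)`` on the term list; the
    optional refinement stage runs Gauss-Newton nonlinear least squares on
    the original height scale (additive error) starting from the screening
    estimates, and falls back to them if it does not converge.

    Raises
    ------
    CollinearTermsError
        If the design matrix is rank deficient (candidate excluded from
        selection).
    ValueError
        If there are fewer than ``n_terms + 2`` observations or any
        non-positive height.
    """
    terms = build_terms(spec)
    y = data["top_height"].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("top heights must be positive")
    n, k = len(y), len(terms)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations, have {n}")
    X = _design_matrix(spec, data)
    logy = np.log(y)
    beta, _, rank, _ = np.linalg.lstsq(X, logy, rcond=None)
    if rank < k:
        raise CollinearTermsError(f"collinear terms in {spec}")
    resid_log = logy - X @ beta
    sse_log = float(resid_log @ resid_log)
    aic = n * math.log(max(sse_log, 1e-300) / n) + 2 * (k + 1)

    refined = False
    if refine:
        refined_beta = _refine_gauss_newton(X, y, beta)
        if refined_beta is not None:
            beta, refined = refined_beta, True

    pred = np.exp(X @ beta)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2 = 0.0  # degenerate: all heights identical
    else:
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
    coefficients = {t: float(b) for t, b in zip(terms, beta)}
    return UrfFit(spec, coefficients, r2, aic, n, refined=refined)


def _refine_gauss_newton(X: np.ndarray, y: np.ndarray,
                         beta0: np.ndarray) -> np.ndarray | None:
    """Original-scale NLS; returns None if it fails to converge."""
    def resid(b):
        return np.exp(X @ b) - y

    def jac(b):
        return np.exp(X @ b)[:, None] * X

    try:
        sol = least_squares(resid, beta0, jac=jac, method="lm",
                            ftol=1e-10, xtol=1e-12, max_nfev=200 * len(beta0))
    except Exception:
        return None
    if not sol.success or not np.all(np.isfinite(sol.x)):
        return None
    return sol.x


def prediction_efficiency(observed, predicted) -> float:
    """EF = 1 - SSE/SST: 1 is perfect, 0 matches the mean-only baseline."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must be equal-length, size >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are all identical (zero denominator)")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / sst


def rmsep(observed, predicted) -> float:
    """Root mean square error of prediction, sqrt(sum((Y - Yhat)^2)/n)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("observed/predicted must be equal-length, size >= 1")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def _fold_assignment(data: pd.DataFrame, k_folds: int,
                     seed: int) -> np.ndarray:
    """Fold labels keyed to a stable observation identifier.

    Rows are ranked by (site_id, population_id) before the seeded shuffle,
    so the assignment — and every CV statistic — is invariant to the row
    order of the input table.
    """
    keys = list(zip(data["site_id"].astype(str),
                    data["population_id"].astype(str),
                    data["top_height"].astype(float)))
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__))
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(len(order))]
    folds = np.empty(len(keys), dtype=int)
    for f, chunk in enumerate(np.array_split(shuffled, k_folds)):
        folds[chunk] = f
    return folds


def _cross_validate(spec: UrfSpec, data: pd.DataFrame,
                    folds: np.ndarray) -> tuple[float, float]:
    """Pooled out-of-fold EF and RMSEP for one candidate (screening fits)."""
    y = data["top_height"].to_numpy(dtype=float)
    pred = np.empty_like(y)
    for f in np.unique(folds):
        train = data[folds != f]
        test = data[folds == f]
        fit = fit_urf(spec, train)
        pred[folds == f] = fit.predict_table(test)
    return prediction_efficiency(y, pred), rmsep(y, pred)


def select_urf(data: pd.DataFrame, prov_pool, site_pool,
               k_folds: int = 10, seed: int = DEFAULT_CV_SEED,
               max_per_side: int = 3, include_intercept: bool = True,
               refine: bool = True):
    """Exhaustive URF selection.

    Fits every candidate by log-scale OLS, keeps the highest original-scale
    R2 within each of the (up to nine) size categories, cross-validates the
    finalists with seeded k-fold assignment, and returns
    ``(per_category, final)`` where ``per_category`` maps (n_prov, n_site)
    to its best fit and ``final`` is the minimum-RMSEP finalist (ties:
    higher EF, then enumeration order), optionally refined by
    original-scale Gauss-Newton.

    Raises
    ------
    ValueError
        If any size category yields no full-rank candidate.
    """
    best: dict[tuple[int, int], UrfFit] = {}
    expected = set()
    for spec in enumerate_specs(prov_pool, site_pool, max_per_side,
                                include_intercept):
        cat = spec.category
        expected.add(cat)
        try:
            fit = fit_urf(spec, data)
        except CollinearTermsError:
            continue
        if cat not in best or fit.r2 > best[cat].r2:
            best[cat] = fit
    missing = sorted(expected - set(best))
    if missing:
        raise ValueError(f"no valid candidate in categor{'y' if len(missing)==1 else 'ies'} {missing}")

    folds = _fold_assignment(data, k_folds, seed)
    cat_order = sorted(best)
    for cat in cat_order:
        fit = best[cat]
        fit.ef_cv, fit.rmsep_cv = _cross_validate(fit.spec, data, folds)

    final = min((best[c] for c in cat_order),
                key=lambda f: (f.rmsep_cv, -f.ef_cv))
    if refine:
        refined = fit_urf(final.spec, data, refine=True)
        refined.ef_cv, refined.rmsep_cv = final.ef_cv, final.rmsep_cv
        best[final.spec.category] = refined
        final = refined
    return best, final
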