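"""Response-function enumeration, fitting, validation metrics, selection."""

import numpy as np
import pandas as pd
import pytest

from climtop.synthetic import default_true_urf, make_urf_dataset
from climtop.urf import (CollinearTermsError, UrfSpec, build_terms,
                         count_candidates, enumerate_specs, fit_urf,
                         prediction_efficiency, rmsep, select_urf)


# --- combinatorics ---------------------------------------------------------

@pytest.mark.parametrize("n_prov,n_site,expected", [
    (14, 17, 390_677),   # lodgepole-pine-sized pools
    (11, 11, 53_361),    # white-spruce-sized pools
    (3, 3, 49),
])
def test_count_candidates(n_prov, n_site, expected):
    assert count_candidates(n_prov, n_site) == expected


def test_count_candidates_max_one():
    assert count_candidates(1, 1, max_per_side=1) == 1


@pytest.mark.parametrize("np_,ns", [(3, 3), (4, 5), (6, 6)])
def test_enumeration_length_matches_count(np_, ns):
    prov = [f"p{i}" for i in range(np_)]
    site = [f"s{i}" for i in range(ns)]
    specs = list(enumerate_specs(prov, site))
    assert len(specs) == count_candidates(np_, ns)
    assert len(set(specs)) == len(specs)


def test_nine_categories_for_pools_of_three_or_more():
    specs = list(enumerate_specs(list("abc"), list("xyz")))
    cats = {s.category for s in specs}
    assert cats == {(p, s) for p in (1, 2, 3) for s in (1, 2, 3)}


def test_enumeration_deterministic():
    prov, site = ["a", "b", "c"], ["x", "y"]
    assert list(enumerate_specs(prov, site)) == list(
        enumerate_specs(prov, site))


# --- term construction -----------------------------------------------------

def test_terms_single_pair_matches_five_coefficient_form():
    spec = UrfSpec(("MAT",), ("MAP",), include_intercept=False)
    assert build_terms(spec) == ["MAT.p", "MAP.s", "MAT.p^2", "MAP.s^2",
                                 "MAT.p:MAP.s"]


@pytest.mark.parametrize("p,s,intercept,n_terms", [
    (3, 3, True, 22),   # 1 + 6 linear + 6 quadratic + 9 cross
    (2, 1, False, 8),   # 3 linear + 3 quadratic + 2 cross
    (1, 1, True, 6),
])
def test_term_counts(p, s, intercept, n_terms):
    spec = UrfSpec(tuple(f"P{i}" for i in range(p)),
                   tuple(f"S{i}" for i in range(s)), intercept)
    terms = build_terms(spec)
    assert len(terms) == n_terms
    # no provenance x provenance or site x site crosses
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            assert a.endswith(".p") and b.endswith(".s")


def test_spec_validation():
    with pytest.raises(ValueError):
        UrfSpec(("A", "A"), ("B",))
    with pytest.raises(ValueError):
        UrfSpec(("A", "B", "C", "D"), ("E",))


# --- fitting ---------------------------------------------------------------

def test_noiseless_recovery(true_urf, noiseless_table):
    fit = fit_urf(true_urf.spec, noiseless_table)
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)
    for term, val in true_urf.coefficients.items():
        assert fit.coefficients[term] == pytest.approx(val, abs=1e-6)


def test_refinement_matches_on_noiseless_data(true_urf, noiseless_table):
    fit = fit_urf(true_urf.spec, noiseless_table, refine=True)
    assert fit.refined
    for term, val in true_urf.coefficients.items():
        assert fit.coefficients[term] == pytest.approx(val, abs=1e-6)


def test_degenerate_constant_heights(true_urf, noiseless_table):
    data = noiseless_table.copy()
    data["top_height"] = 7.0
    fit = fit_urf(true_urf.spec, data)
    assert fit.r2 == 0.0  # convention for zero total variance
    prov = {"MAT": data["MAT.p"].iloc[0]}
    site = {"MAT": data["MAT.s"].iloc[0]}
    assert fit.predict(prov, site) == pytest.approx(7.0, rel=1e-6)


def test_collinear_terms_rejected(noiseless_table):
    data = noiseless_table.copy()
    data["MWMT.p"] = 2.0 * data["MAT.p"]   # exact linear copy
    spec = UrfSpec(("MAT", "MWMT"), ("MAT",))
    with pytest.raises(CollinearTermsError):
        fit_urf(spec, data)


def test_prediction_round_trip(true_urf):
    h = true_urf.predict({"MAT": 1.0}, {"MAT": 3.0})
    z = (2.3 + 0.05 * 1 + 0.08 * 3 - 0.010 * 1 - 0.012 * 9 + 0.004 * 3)
    assert h == pytest.approx(np.exp(z), rel=1e-12)


# --- validation metrics ----------------------------------------------------

def test_prediction_efficiency_closed_forms():
    assert prediction_efficiency([1, 2, 3], [1, 2, 3]) == 1.0
    assert prediction_efficiency([1, 2, 3], [2, 2, 2]) == 0.0
    assert prediction_efficiency([1, 2, 3], [1, 2, 5]) == pytest.approx(
        -1.0, abs=1e-12)
    with pytest.raises(ValueError):
        prediction_efficiency([2, 2], [1, 3])


def test_rmsep_closed_forms():
    assert rmsep([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmsep([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
        np.sqrt(25 / 2), abs=1e-12)
    # homogeneity: doubling residuals doubles RMSEP
    assert rmsep([0, 0], [6.0, 8.0]) == pytest.approx(
        2 * rmsep([0, 0], [3.0, 4.0]), abs=1e-12)


# --- selection -------------------------------------------------------------

def test_select_single_spec_pool(true_urf):
    table, _ = make_urf_dataset(true_urf, 15, 15, 0.05, seed=5)
    per_cat, final = select_urf(table, ["MAT"], ["MAT"], seed=1)
    assert list(per_cat) == [(1, 1)]
    assert final.spec == UrfSpec(("MAT",), ("MAT",))
    assert final.rmsep_cv >= 0 and final.ef_cv <= 1


def test_select_deterministic_same_seed(true_urf):
    table, _ = make_urf_dataset(true_urf, 15, 15, 0.05, seed=6,
                                extra_prov_vars=["TD"],
                                extra_site_vars=["MAP"])
    r1 = select_urf(table, ["MAT", "TD"], ["MAT", "MAP"], seed=9)
    r2 = select_urf(table, ["MAT", "TD"], ["MAT", "MAP"], seed=9)
    assert r1[1].spec == r2[1].spec
    assert r1[1].rmsep_cv == r2[1].rmsep_cv
    assert r1[1].ef_cv == r2[1].ef_cv


def test_select_invariant_to_row_order(true_urf):
    table, _ = make_urf_dataset(true_urf, 12, 12, 0.05, seed=8,
                                extra_prov_vars=["TD"],
                                extra_site_vars=["MAP"])
    shuffled = table.sample(frac=1, random_state=4).reset_index(drop=True)
    r1 = select_urf(table, ["MAT", "TD"], ["MAT", "MAP"], seed=2)
    r2 = select_urf(shuffled, ["MAT", "TD"], ["MAT", "MAP"], seed=2)
    assert r1[1].spec == r2[1].spec
    assert r1[1].rmsep_cv == pytest.approx(r2[1].rmsep_cv, rel=1e-9)


def test_fold_assignment_partitions_once(true_urf):
    from climtop.urf import _fold_assignment
    table, _ = make_urf_dataset(true_urf, 10, 10, 0.05, seed=3)
    folds = _fold_assignment(table, 10, seed=1)
    assert len(folds) == len(table)
    assert set(folds) == set(range(10))
    assert np.bincount(folds).sum() == len(table)


def test_training_ef_of_category_winner_is_maximal(true_urf):
    """Within a category the retained fit has the max original-scale R2."""
    table, _ = make_urf_dataset(true_urf, 15, 15, 0.08, seed=10,
                                extra_prov_vars=["TD"],
                                extra_site_vars=["MAP"])
    per_cat, _ = select_urf(table, ["MAT", "TD"], ["MAT", "MAP"], seed=3,
                            refine=False)
    for cat, best in per_cat.items():
        for spec in enumerate_specs(["MAT", "TD"], ["MAT", "MAP"]):
            if spec.category != cat:
                continue
            try:
                fit = fit_urf(spec, table)
            except CollinearTermsError:
                continue
            assert best.r2 >= fit.r2 - 1e-12


def test_serialisation_round_trip(true_urf, noiseless_table, tmp_path):
    from climtop.urf import UrfFit
    fit = fit_urf(true_urf.spec, noiseless_table)
    path = tmp_path / "urf.json"
    fit.to_json(path)
    back = UrfFit.from_json(path)
    assert back.spec == fit.spec
    assert back.coefficients == fit.coefficients
    assert back.predict({"MAT": 1.0}, {"MAT": 2.0}) == pytest.approx(
        fit.predict({"MAT": 1.0}, {"MAT": 2.0}), rel=1e-12)
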