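"""Curve assembly: constant-climate equivalence, directionality, causality."""

import numpy as np
import pandas as pd
import pytest

from climtop.climate import ClimateSeries, constant_series
from climtop.curves import build_curve, site_index_at_50
from climtop.gypsy import evaluate_top_height, invert_site_index
from climtop.urf import UrfFit, UrfSpec


def _simple_urf(slope: float, level: float = 2.2) -> UrfFit:
    """Log-linear response in site MAT only (monotone, sign of `slope`)."""
    spec = UrfSpec(("MAT",), ("MAT",))
    coefficients = {"Intercept": level, "MAT.p": 0.0, "MAT.s": slope,
                    "MAT.p^2": 0.0, "MAT.s^2": 0.0, "MAT.p:MAT.s": 0.0}
    return UrfFit(spec, coefficients, 1.0, np.nan, 0)


def _warming_series(start=1.0, rate=0.05, n=90, year0=1980):
    years = np.arange(year0, year0 + n)
    mat = start + rate * np.arange(n)
    return ClimateSeries("W1", pd.DataFrame({"MAT": mat}, index=years))


@pytest.mark.parametrize("mat", [-1.0, 1.5, 4.0])
def test_constant_climate_reproduces_static_curve(species_params, true_urf,
                                                  mat):
    """The defining oracle: constant climate collapses to the static curve."""
    normals = {"MAT": mat}
    series = constant_series("S1", normals, 1980, 80)
    curve = build_curve(species_params, true_urf, normals, series, 1980,
                        ages=80)
    ht_common = true_urf.predict(normals, normals)
    si = invert_site_index(species_params, ht_common,
                           species_params.common_age)
    static = evaluate_top_height(species_params, si, np.arange(1, 81))
    assert np.max(np.abs(curve.heights - static)) < 1e-9
    assert np.max(np.abs(curve.si_profile - si)) < 1e-8


def test_warming_with_increasing_urf_lifts_curve(species_params):
    urf = _simple_urf(+0.06)
    warm = _warming_series()
    base = constant_series("W1", {"MAT": 1.0}, 1980, 90)
    prov = {"MAT": 1.0}
    hot = build_curve(species_params, urf, prov, warm, 1980, ages=80)
    ncc = build_curve(species_params, urf, prov, base, 1980, ages=80)
    assert np.all(hot.heights >= ncc.heights - 1e-12)
    assert hot.heights[-1] > ncc.heights[-1]


def test_warming_with_decreasing_urf_depresses_curve(species_params):
    urf = _simple_urf(-0.06)
    warm = _warming_series()
    base = constant_series("W1", {"MAT": 1.0}, 1980, 90)
    prov = {"MAT": 1.0}
    hot = build_curve(species_params, urf, prov, warm, 1980, ages=80)
    ncc = build_curve(species_params, urf, prov, base, 1980, ages=80)
    assert np.all(hot.heights <= ncc.heights + 1e-12)
    assert hot.heights[-1] < ncc.heights[-1]


def test_heights_non_decreasing_and_bounded(species_params, true_urf):
    curve = build_curve(species_params, true_urf, {"MAT": 2.0},
                        _warming_series(), 1980, ages=80)
    assert np.all(np.diff(curve.heights) >= 0)
    bound = evaluate_top_height(species_params, curve.si_profile.max(),
                                curve.ages.astype(float))
    assert np.all(curve.heights <= bound + 1e-9)


def test_si50_accessor_and_constant_case(species_params):
    urf = _simple_urf(0.0)
    normals = {"MAT": 1.0}
    # pick the MAT level whose static curve has SI exactly 18
    target_ln = np.log(18.0)
    ht_common = evaluate_top_height(species_params, 18.0,
                                    species_params.common_age)
    urf.coefficients["Intercept"] = float(np.log(ht_common))
    series = constant_series("S1", normals, 1980, 60)
    curve = build_curve(species_params, urf, normals, series, 1980, ages=60)
    assert site_index_at_50(curve) == pytest.approx(18.0, abs=1e-9)
    assert curve.si50 == curve.heights[curve.ages == 50][0]


def test_si50_requires_age_50(species_params, true_urf):
    series = constant_series("S1", {"MAT": 1.0}, 1980, 40)
    curve = build_curve(species_params, true_urf, {"MAT": 1.0}, series,
                        1980, ages=40)
    with pytest.raises(ValueError, match="50"):
        site_index_at_50(curve)


def test_climate_after_age_50_cannot_affect_si50(species_params, true_urf):
    """Causality: scenarios differing only after year 50 share heights[:50]."""
    years = np.arange(1980, 2060)
    mat_a = np.full(80, 2.0)
    mat_b = mat_a.copy()
    mat_b[50:] += 5.0
    sa = ClimateSeries("S1", pd.DataFrame({"MAT": mat_a}, index=years))
    sb = ClimateSeries("S1", pd.DataFrame({"MAT": mat_b}, index=years))
    prov = {"MAT": 2.0}
    ca = build_curve(species_params, true_urf, prov, sa, 1980, ages=80)
    cb = build_curve(species_params, true_urf, prov, sb, 1980, ages=80)
    assert site_index_at_50(ca) == site_index_at_50(cb)
    assert np.array_equal(ca.heights[:50], cb.heights[:50])
    assert not np.array_equal(ca.heights[50:], cb.heights[50:])


def test_curve_depends_on_site_climate_only_through_running_average(
        species_params, true_urf):
    """Permuting years before age i only acts through the lifespan averages."""
    years = np.arange(1980, 2040)
    rng = np.random.default_rng(0)
    mat = 2.0 + rng.normal(0, 1.0, 60)
    mat_perm = mat.copy()
    mat_perm[:20] = mat[:20][::-1]  # same first-20 average, different order
    sa = ClimateSeries("S1", pd.DataFrame({"MAT": mat}, index=years))
    sb = ClimateSeries("S1", pd.DataFrame({"MAT": mat_perm}, index=years))
    prov = {"MAT": 2.0}
    ca = build_curve(species_params, true_urf, prov, sa, 1980, ages=60)
    cb = build_curve(species_params, true_urf, prov, sb, 1980, ages=60)
    # averages over years 1..i coincide for every i >= 20, so the solved SI
    # and all later increments coincide; earlier SI values differ
    assert np.allclose(ca.si_profile[19:], cb.si_profile[19:], atol=1e-12)
    assert np.allclose(ca.heights[20:] - ca.heights[19],
                       cb.heights[20:] - cb.heights[19], atol=1e-9)
    assert not np.allclose(ca.si_profile[:19], cb.si_profile[:19])


def test_determinism_bit_identical(species_params, true_urf):
    series = _warming_series()
    c1 = build_curve(species_params, true_urf, {"MAT": 1.0}, series, 1980,
                     ages=70)
    c2 = build_curve(species_params, true_urf, {"MAT": 1.0}, series, 1980,
                     ages=70)
    assert np.array_equal(c1.heights, c2.heights)
    assert np.array_equal(c1.si_profile, c2.si_profile)


def test_smoothing_produces_monotone_climate_path(species_params, true_urf):
    rng = np.random.default_rng(1)
    years = np.arange(1980, 2060)
    mat = 1.0 + 0.03 * np.arange(80) + rng.normal(0, 0.8, 80)
    series = ClimateSeries("S1", pd.DataFrame({"MAT": mat}, index=years))
    rough = build_curve(species_params, true_urf, {"MAT": 1.0}, series,
                        1980, ages=80, smooth=False)
    smooth = build_curve(species_params, true_urf, {"MAT": 1.0}, series,
                         1980, ages=80, smooth=True)
    # smoothed SI path has strictly fewer direction changes
    def wiggles(x):
        return int(np.sum(np.diff(np.sign(np.diff(x))) != 0))
    assert wiggles(smooth.si_profile) < wiggles(rough.si_profile)


def test_curve_frame_columns(species_params, true_urf):
    series = constant_series("S1", {"MAT": 1.0}, 1980, 55)
    curve = build_curve(species_params, true_urf, {"MAT": 1.0}, series,
                        1980, ages=55)
    frame = curve.to_frame()
    assert list(frame.columns) == ["age", "si_i", "height_m"]
    assert len(frame) == 55
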