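"""Standardization, weighting, natural breaks, classification, ratings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vulnstrat as vs
from vulnstrat.indices import (
    AggregationError,
    ClassificationError,
    DegenerateIndicatorError,
    StandardizationSpec,
)
from vulnstrat.study_model import UnitValidationError

from helpers import brute_force_jenks


# ---------------------------------------------------------------------------
# standardize
# ---------------------------------------------------------------------------

def test_standardize_endpoints_and_interior():
    out = vs.standardize([2.0, 4.0, 10.0])
    assert out[0] == 0.0
    assert out[2] == 10.0
    assert out[1] == pytest.approx(10 * (4 - 2) / (10 - 2))  # 2.5


def test_standardize_degenerate_indicator_is_an_error():
    with pytest.raises(DegenerateIndicatorError):
        vs.standardize([3.0, 3.0, 3.0])


def test_standardize_idempotent_on_own_scale():
    vals = np.array([1.0, 4.0, 9.5, 0.0, 10.0])
    once = vs.standardize(vals)
    twice = vs.standardize(once)
    np.testing.assert_allclose(once, twice)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=2,
        max_size=30,
    ).filter(lambda v: max(v) - min(v) > 1e-6)
)
def test_standardize_preserves_rank_order(values):
    out = vs.standardize(values)
    assert np.all((out >= 0) & (out <= 10))
    # affine map: non-decreasing along the sorted input order (float
    # precision may collapse, but never invert, near-ties)
    assert np.all(np.diff(out[np.argsort(values, kind="stable")]) >= -1e-12)


# ---------------------------------------------------------------------------
# population-weighted mean
# ---------------------------------------------------------------------------

def test_weighted_mean_identity_and_symmetry():
    assert vs.population_weighted_mean([7.3], [811]) == 7.3
    assert vs.population_weighted_mean([2.0, 6.0], [500, 500]) == 4.0


def test_weighted_mean_hand_value():
    assert vs.population_weighted_mean([0.0, 10.0], [1000, 3000]) == 7.5


def test_weighted_mean_zero_population_errors():
    with pytest.raises(AggregationError):
        vs.population_weighted_mean([1.0, 2.0], [0, 0])
    with pytest.raises(UnitValidationError):
        vs.population_weighted_mean([1.0, 2.0], [1.0])


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def test_orientation_identity_and_reflection():
    np.testing.assert_allclose(vs.orient_indicator([3.2], +1), [3.2])
    np.testing.assert_allclose(vs.orient_indicator([0.0], -1), [10.0])
    np.testing.assert_allclose(vs.orient_indicator([2.5], -1), [7.5])


def test_orientation_rejects_out_of_range():
    with pytest.raises(UnitValidationError):
        vs.orient_indicator([11.0], -1)


# ---------------------------------------------------------------------------
# composite index
# ---------------------------------------------------------------------------

def test_composite_constant_row_is_fixed_point():
    m = np.full((4, 3), 6.25)
    np.testing.assert_allclose(vs.composite_index(m, [0.2, 0.5, 0.3]), 6.25)


def test_composite_degenerate_weight_selects_column():
    m = np.array([[1.0, 9.0, 4.0], [2.0, 8.0, 5.0]])
    np.testing.assert_allclose(vs.composite_index(m, [1, 0, 0]), m[:, 0])


def test_composite_hand_value():
    out = vs.composite_index(np.array([[4.0, 8.0]]), [0.25, 0.75])
    assert out[0] == pytest.approx(7.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.01, max_value=5.0), min_size=2, max_size=6),
    st.floats(min_value=0.1, max_value=50.0),
)
def test_composite_invariant_to_weight_rescaling(weights, scale):
    rng = np.random.default_rng(7)
    m = rng.uniform(0, 10, size=(5, len(weights)))
    base = vs.composite_index(m, weights)
    scaled = vs.composite_index(m, [w * scale for w in weights])
    np.testing.assert_allclose(base, scaled, rtol=1e-9)


def test_composite_missing_cell_is_an_error():
    m = np.array([[1.0, np.nan]])
    with pytest.raises(UnitValidationError, match="missing"):
        vs.composite_index(m, [0.5, 0.5])


# ---------------------------------------------------------------------------
# natural breaks + classification
# ---------------------------------------------------------------------------

def test_jenks_single_class_has_no_cuts():
    assert vs.jenks_breaks([1.0, 5.0, 9.0], 1).size == 0


def test_jenks_separates_obvious_clusters():
    np.testing.assert_allclose(vs.jenks_breaks([1, 2, 10, 11], 2), [2.0])
    np.testing.assert_allclose(
        vs.jenks_breaks([1, 2, 3, 10, 11, 12, 30, 31, 32], 3), [3.0, 12.0]
    )


def test_jenks_requires_enough_distinct_values():
    with pytest.raises(ClassificationError):
        vs.jenks_breaks([1.0, 1.0, 1.0], 2)


@pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (9, 3, 1), (12, 4, 2), (10, 3, 3), (12, 3, 4)])
def test_jenks_matches_exhaustive_oracle(n, k, seed):
    """The dynamic program reproduces the brute-force optimal SSD."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 100, size=n)
    oracle_ssd, _ = brute_force_jenks(values, k)
    breaks = vs.jenks_breaks(values, k)
    classes = vs.classify(values, breaks)
    impl_ssd = sum(
        ((values[classes == c] - values[classes == c].mean()) ** 2).sum()
        for c in np.unique(classes)
    )
    assert impl_ssd == pytest.approx(oracle_ssd, abs=1e-9)


def test_classify_boundaries_go_to_lower_class():
    breaks = [2.0, 5.0]
    np.testing.assert_array_equal(vs.classify([1.0, 2.0, 2.1, 5.0, 5.1], breaks), [1, 1, 2, 2, 3])


def test_classify_extremes():
    breaks = [1.0, 2.0, 3.0, 4.0]
    assert vs.classify([0.0], breaks)[0] == 1
    assert vs.classify([99.0], breaks)[0] == 5


# ---------------------------------------------------------------------------
# vulnerability ratings
# ---------------------------------------------------------------------------

def test_rating_extremes_are_labelled():
    assert vs.vulnerability_rating(1, 5).label == "best"
    assert vs.vulnerability_rating(5, 1).label == "worst"
    assert vs.vulnerability_rating(3, 3).label is None


def test_exactly_25_distinct_ratings():
    ratings = vs.VulnerabilityRating.all_ratings()
    assert len(ratings) == len(set(ratings)) == 25


def test_rating_rejects_out_of_range():
    with pytest.raises(UnitValidationError):
        vs.vulnerability_rating(0, 3)


# ---------------------------------------------------------------------------
# end-to-end index construction
# ---------------------------------------------------------------------------

def _extreme_area():
    """Units engineered so one is lowest-hazard/highest-capacity and its
    mirror is the opposite; the rest fill the middle."""
    rng = np.random.default_rng(5)
    units = []
    n = 30
    for i in range(n):
        if i == 0:
            u_h, u_a = 0.0, 1.0  # pristine: no hazard, full capacity
        elif i == 1:
            u_h, u_a = 1.0, 0.0  # industrial core
        else:
            u_h = rng.uniform(0.2, 0.8)
            u_a = rng.uniform(0.2, 0.8)
        raw = {}
        for s in vs.DEFAULT_H_INDICATORS:
            raw[s.name] = u_h
        for s in vs.DEFAULT_A_INDICATORS:
            raw[s.name] = s.polarity * u_a
        units.append(
            vs.SpatialUnit(
                unit_id=f"u{i:02d}", name=f"u{i}", population=1000, mos=50, raw_indicators=raw
            )
        )
    return vs.StudyArea(units)


def test_extreme_units_receive_extreme_ratings():
    area = _extreme_area()
    vs.compute_indices(area, vs.DEFAULT_INDICATORS)
    best = area["u00"]
    worst = area["u01"]
    assert (best.h_class, best.a_class) == (1, 5)
    assert (worst.h_class, worst.a_class) == (5, 1)
    assert best.h_s == 0.0 and best.a_s == 10.0
    assert worst.h_s == 10.0 and worst.a_s == 0.0


def test_both_standardization_orders_supported():
    area1 = _bg_area()
    area2 = _bg_area()
    vs.compute_indices(area1, vs.DEFAULT_INDICATORS, order="aggregate_then_standardize")
    vs.compute_indices(area2, vs.DEFAULT_INDICATORS, order="standardize_then_aggregate")
    h1 = [u.h_s for u in sorted(area1.top_units, key=lambda u: u.unit_id)]
    h2 = [u.h_s for u in sorted(area2.top_units, key=lambda u: u.unit_id)]
    # same rank order of towns either way on noise-free nested data
    np.testing.assert_array_equal(np.argsort(h1), np.argsort(h2))


def _bg_area():
    units = []
    rng = np.random.default_rng(11)
    for t in range(8):
        units.append(vs.SpatialUnit(unit_id=f"t{t}", name=f"t{t}", scale="town"))
        level = t / 7
        for b in range(3):
            raw = {}
            for s in vs.DEFAULT_H_INDICATORS:
                raw[s.name] = level + 0.01 * b
            for s in vs.DEFAULT_A_INDICATORS:
                raw[s.name] = s.polarity * (1 - level) + 0.01 * b
            units.append(
                vs.SpatialUnit(
                    unit_id=f"t{t}b{b}",
                    name=f"t{t}b{b}",
                    scale="block_group",
                    parent_id=f"t{t}",
                    population=float(rng.integers(500, 2000)),
                    mos=30,
                    raw_indicators=raw,
                )
            )
    return vs.StudyArea(units)
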