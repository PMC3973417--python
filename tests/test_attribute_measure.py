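import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilfert import ValidationError, measure_table, single_index_measure, tensor_to_long
from soilfert.attribute_measure import MeasureTensor

from conftest import random_boundaries


def midpoint_oracle(x, boundaries):
    """Independent scalar evaluation of midpoint-anchored membership.

    Builds the descending knot sequence (edge anchor, boundaries at 0.5,
    interval midpoints at 1) explicitly and interpolates the membership
    *vectors* between bracketing knots — a different code path from the
    per-grade interpolation in the implementation.
    """
    b = list(map(float, boundaries))
    k = len(b) + 1
    anchors = [b[0] + (b[0] - b[1]) / 2 if k >= 3 else 1.5 * b[0]]
    anchors += [(b[i] + b[i + 1]) / 2 for i in range(k - 2)]
    anchors += [b[-1] / 2]
    knots = []  # (position, membership vector), descending
    for g in range(k):
        e = np.zeros(k)
        e[g] = 1.0
        knots.append((anchors[g], e))
        if g < k - 1:
            half = np.zeros(k)
            half[g] = half[g + 1] = 0.5
            knots.append((b[g], half))
    if x >= knots[0][0]:
        return knots[0][1]
    if x <= knots[-1][0]:
        return knots[-1][1]
    for (hi, vhi), (lo, vlo) in zip(knots, knots[1:]):
        if lo <= x <= hi:
            f = (x - lo) / (hi - lo)
            return f * vhi + (1 - f) * vlo
    raise AssertionError("unreachable")


def test_frozen_example_two_grade_support():
    # boundaries (30, 20, 10): anchors 35, 25, 15, 5; x = 22 sits between
    # the grade-2 and grade-3 anchors -> (0, 0.7, 0.3, 0)
    mu = single_index_measure(22.0, (30, 20, 10))
    assert np.allclose(mu, [0.0, 0.7, 0.3, 0.0], atol=1e-12)


def test_boundary_value_splits_half_half_even_with_unequal_intervals():
    for b in [(30, 20, 10), (30, 20, 5), (100, 10, 9)]:
        for g, x in enumerate(b):
            mu = single_index_measure(float(x), b)
            expected = np.zeros(len(b) + 1)
            expected[g] = expected[g + 1] = 0.5
            assert np.allclose(mu, expected, atol=1e-12)


def test_saturation_beyond_outer_anchors():
    assert np.allclose(single_index_measure(1e6, (30, 20, 10)), [1, 0, 0, 0])
    assert np.allclose(single_index_measure(0.0, (30, 20, 10)), [0, 0, 0, 1])
    # lower_is_better mirrors
    assert np.allclose(
        single_index_measure(1e6, (10, 20, 30), orientation="lower_is_better"),
        [0, 0, 0, 1],
    )


def test_dense_grid_matches_independent_oracle(rng):
    for k in (2, 3, 4, 6):
        b = random_boundaries(rng, k)
        xs = np.linspace(0.0, 1.5 * b[0], 2000)
        impl = single_index_measure(xs, b)
        orc = np.array([midpoint_oracle(x, b) for x in xs])
        np.testing.assert_allclose(impl, orc, atol=1e-10)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    data=st.data(),
    k=st.integers(min_value=2, max_value=8),
    anchor=st.sampled_from(["midpoint", "boundary"]),
)
def test_measure_is_a_two_adjacent_grade_distribution(data, k, anchor):
    seed = data.draw(st.integers(0, 2**32 - 1))
    r = np.random.default_rng(seed)
    b = random_boundaries(r, k)
    x = r.uniform(0.0, 2.0 * b[0])
    mu = single_index_measure(x, b, anchor=anchor)
    assert np.all(mu >= 0) and np.all(mu <= 1)
    assert abs(mu.sum() - 1.0) < 1e-9
    support = np.nonzero(mu > 0)[0]
    assert support.size <= 2
    if support.size == 2:
        assert support[1] - support[0] == 1


def test_cumulative_measure_is_monotone_in_x(rng):
    for anchor in ("midpoint", "boundary"):
        b = random_boundaries(rng, 6)
        xs = np.sort(rng.uniform(0.0, 1.5 * b[0], size=500))
        mu = single_index_measure(xs, b, anchor=anchor)
        cum = np.cumsum(mu, axis=1)
        # larger x -> stochastically better grade (cumulative no smaller)
        assert np.all(np.diff(cum, axis=0) >= -1e-12)


def test_orientation_symmetry(rng):
    b = random_boundaries(rng, 5)
    xs = rng.uniform(0.0, 1.5 * b[0], size=200)
    hib = single_index_measure(xs, b, "higher_is_better")
    lib = single_index_measure(xs, b[::-1], "lower_is_better")
    np.testing.assert_allclose(lib, hib[:, ::-1], atol=0)


def test_invalid_values_rejected():
    with pytest.raises(ValidationError):
        single_index_measure(-1.0, (30, 20, 10))
    with pytest.raises(ValidationError):
        single_index_measure(np.nan, (30, 20, 10))


def test_measure_table_matches_scalar_and_is_equivariant(standard, fixture_table):
    mt = measure_table(fixture_table, standard)
    assert mt.values.shape == (52, 6, 6)
    sums = mt.values.sum(axis=2)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)
    # one row reproduces the scalar function per index
    row = fixture_table.iloc[7]
    i = list(mt.sample_ids).index(row["sample_id"])
    for j, name in enumerate(mt.index_names):
        spec = standard.spec(name)
        np.testing.assert_allclose(
            mt.values[i, j],
            single_index_measure(row[name], standard.boundaries[name], spec.orientation),
        )
    # permuting sample rows permutes tensor slices identically
    perm = np.random.default_rng(3).permutation(len(fixture_table))
    mt2 = measure_table(fixture_table.iloc[perm], standard)
    np.testing.assert_array_equal(mt2.values, mt.values[perm])


def test_missing_value_policy(standard, fixture_table):
    broken = fixture_table.copy()
    broken.loc[broken.index[3], "SOM"] = np.nan
    with pytest.raises(ValidationError, match="missing"):
        measure_table(broken, standard)
    dropped = measure_table(broken, standard, missing="drop")
    assert dropped.values.shape[0] == 51


def test_long_format_export_round_trips_values(standard, fixture_table):
    mt = measure_table(fixture_table.head(3), standard)
    long = tensor_to_long(mt)
    assert list(long.columns) == ["sample_id", "index", "grade", "measure"]
    assert len(long) == 3 * 6 * 6
    back = long["measure"].to_numpy().reshape(3, 6, 6)
    np.testing.assert_array_equal(back, mt.values)
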