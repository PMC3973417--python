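import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilfert import (
    ValidationError,
    WeightVector,
    letter_display,
    oneway_anova,
    summarize,
    summary_table,
    weight_spread,
)

from conftest import small_table


def anova_from_summaries(means, sds, ns):
    """Summary-statistics one-way F: an independent route to the same test."""
    means, sds, ns = map(np.asarray, (means, sds, ns))
    grand = np.sum(ns * means) / ns.sum()
    msb = np.sum(ns * (means - grand) ** 2) / (len(ns) - 1)
    msw = np.sum((ns - 1) * sds**2) / (ns.sum() - len(ns))
    f = msb / msw
    return f, float(stats.f.sf(f, len(ns) - 1, int(ns.sum()) - len(ns)))


def test_summarize_constant_group_and_manual_example():
    t = small_table({"g1": [[2, 1], [2, 4], [2, 7]], "g2": [[5, 2], [7, 2]]})
    s = {x.group: x for x in summarize(t)}
    assert s["g1"].mean["A"] == 2 and s["g1"].sd["A"] == 0 and s["g1"].cv["A"] == 0
    # hand-computed: mean 4, sd sqrt(((1-4)^2+(0)^2+(3)^2)/2) = 3
    assert s["g1"].mean["B"] == pytest.approx(4.0)
    assert s["g1"].sd["B"] == pytest.approx(3.0)
    assert s["g1"].cv["B"] == pytest.approx(0.75)
    assert s["g2"].mean["A"] == pytest.approx(6.0)
    assert s["g2"].sd["A"] == pytest.approx(np.sqrt(2.0))
    with pytest.raises(ValidationError):
        summarize(small_table({"g1": [[1, 1]], "g2": [[2, 2], [3, 3]]}))


def test_summarize_recovers_generator_moments(standard):
    import soilfert as sf

    spec = sf.GroupSpec(
        label="farmland",
        means={n: m for n, (m, _) in sf.synthetic_data.LAND_USE_PARAMS["farmland"].items()},
        cvs={n: c for n, (_, c) in sf.synthetic_data.LAND_USE_PARAMS["farmland"].items()},
        n=10_000,
    )
    t = sf.generate_groups([spec], seed=11)
    s = summarize(t)[0]
    assert s.mean["SOM"] == pytest.approx(6.87, rel=0.02)
    assert s.cv["SOM"] == pytest.approx(0.30, rel=0.05)


def test_summarize_is_permutation_invariant(fixture_table):
    a = summary_table(summarize(fixture_table))
    b = summary_table(summarize(fixture_table.sample(frac=1.0, random_state=5)))
    pd.testing.assert_frame_equal(a, b)


def test_anova_identical_groups_and_degenerate_rules():
    t = small_table({"g1": [[1, 0], [2, 0]], "g2": [[1, 0], [2, 0]]})
    a = oneway_anova(t, "A")
    assert a.F == 0.0 and a.p == 1.0
    assert a.df_between == 1 and a.df_within == 2
    # zero within-variance, different means -> p = 0
    t2 = small_table({"g1": [[1, 0], [1, 0]], "g2": [[2, 0], [2, 0]]})
    assert oneway_anova(t2, "A").p == 0.0
    # all identical -> p = 1
    assert oneway_anova(t2, "B").p == 1.0


def test_two_group_anova_equals_squared_t(rng):
    x = rng.normal(5.0, 1.0, size=8)
    y = rng.normal(6.0, 1.0, size=6)
    t = small_table({"g1": [[v, 0] for v in x], "g2": [[v, 0] for v in y]})
    a = oneway_anova(t, "A")
    tstat, pt = stats.ttest_ind(x, y, equal_var=True)
    assert a.F == pytest.approx(tstat**2, rel=1e-12)
    assert a.p == pytest.approx(pt, rel=1e-10)


def test_anova_matches_summary_statistics_oracle(rng):
    for _ in range(500):
        g = rng.integers(2, 6)
        groups = {
            f"g{i}": [[v] for v in rng.normal(rng.uniform(0, 3), 1.0, size=rng.integers(3, 9))]
            for i in range(g)
        }
        t = small_table(groups, index_names=("A",))
        a = oneway_anova(t, "A")
        means = [np.mean([r[0] for r in v]) for v in groups.values()]
        sds = [np.std([r[0] for r in v], ddof=1) for v in groups.values()]
        ns = [len(v) for v in groups.values()]
        f, p = anova_from_summaries(means, sds, ns)
        assert a.F == pytest.approx(f, abs=1e-10, rel=1e-10)
        assert a.p == pytest.approx(p, abs=1e-10)
        assert 0.0 <= a.p <= 1.0


def test_anova_invariance_to_shift_and_scale(rng):
    t = small_table(
        {f"g{i}": [[v] for v in rng.normal(i, 1, 5)] for i in range(3)},
        index_names=("A",),
    )
    base = oneway_anova(t, "A")
    t2 = t.assign(A=3.0 * t["A"] + 100.0)
    shifted = oneway_anova(t2, "A")
    assert shifted.F == pytest.approx(base.F, rel=1e-9)
    assert shifted.p == pytest.approx(base.p, rel=1e-9)


def test_letters_all_shared_when_groups_identical():
    t = small_table({"g1": [[1], [2], [3]], "g2": [[1], [2], [3]], "g3": [[2], [1], [3]]},
                    index_names=("A",))
    letters = letter_display(t, "A")
    assert set(letters.values()) == {"a"}


def test_letters_separate_distant_groups():
    t = small_table(
        {"lo": [[1.0], [1.1], [0.9]], "hi": [[100.0], [101.0], [99.0]]},
        index_names=("A",),
    )
    letters = letter_display(t, "A")
    assert letters["hi"] == "a" and letters["lo"] == "b"


def test_letters_consistent_with_pairwise_significance(rng):
    from soilfert.group_stats import _pairwise_lsd_p

    for trial in range(30):
        t = small_table(
            {
                f"g{i}": [[v] for v in rng.normal(rng.uniform(0, 2.5), 1.0, 5)]
                for i in range(5)
            },
            index_names=("A",),
        )
        letters = letter_display(t, "A", alpha=0.05)
        labels, _, pmat = _pairwise_lsd_p(t, "A")
        for i, j in itertools.combinations(range(len(labels)), 2):
            shared = set(letters[labels[i]]) & set(letters[labels[j]])
            if pmat[i, j] < 0.05:
                assert not shared, (letters, pmat)
            else:
                assert shared, (letters, pmat)


def make_wv(weights):
    w = np.asarray(weights, dtype=float)
    return WeightVector("g", tuple(f"x{i}" for i in range(w.size)), w / w.sum())


def test_weight_spread_formulas_and_errors():
    assert weight_spread(make_wv([1, 1, 1, 1])).spread_pct == 0.0
    wv = make_wv([20, 10, 10, 10])
    assert weight_spread(wv, "range_over_min").spread_pct == pytest.approx(100.0)
    assert weight_spread(wv, "range_over_mean").spread_pct == pytest.approx(
        (0.4 - 0.2) / 0.25 * 100
    )
    with pytest.raises(ValidationError, match="range_over_mean"):
        weight_spread(make_wv([1.0, 1.0, 0.0]), "range_over_min")


def test_weight_spread_positive_iff_nonuniform(rng):
    for _ in range(50):
        w = rng.uniform(0.1, 1.0, size=6)
        wv = make_wv(w)
        sp = weight_spread(wv).spread_pct
        if np.allclose(wv.weights, wv.weights[0]):
            assert sp == 0.0
        else:
            assert sp > 0.0
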