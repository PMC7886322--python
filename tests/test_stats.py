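"""Nonparametric tests and the noncentral-t sample-size computation."""
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from subtendon import (kruskal_wallis, mann_whitney_exact,
                       sample_size_two_group_t, two_sample_t_power)

LG_CSA = [13.6, 12.4, 5.7, 10.4, 4.6]
MG_CSA = [14.5, 10.8, 10.7, 14.0, 17.0]
SOL_CSA = [39.2, 20.6, 30.9, 38.2, 35.2]


def brute_force_two_sided_p(a, b):
    """Independent enumeration oracle: doubled smaller tail of the rank sum."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    ranks = sps.rankdata(np.concatenate([a, b]))
    obs = ranks[:len(a)].sum()
    sums = [sum(ranks[list(c)])
            for c in combinations(range(len(ranks)), len(a))]
    sums = np.asarray(sums)
    lo = np.mean(sums <= obs + 1e-9)
    hi = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


def test_mann_whitney_complete_separation():
    """Fully separated groups of five give U = 0 and p = 2/252."""
    res = mann_whitney_exact(LG_CSA, SOL_CSA)
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 252)


def test_mann_whitney_small_examples():
    assert mann_whitney_exact([1.0], [1.0]).p_value == pytest.approx(1.0)
    res = mann_whitney_exact([1.0, 2.0], [3.0, 4.0])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 6)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=6),
    st.lists(st.integers(min_value=0, max_value=8), min_size=2, max_size=6),
)
def test_mann_whitney_matches_enumeration_oracle(a, b):
    """Exact p agrees with an independent full enumeration (ties included)."""
    res = mann_whitney_exact(a, b)
    assert res.p_value == pytest.approx(brute_force_two_sided_p(a, b))


def test_mann_whitney_matches_scipy_without_ties():
    rng = np.random.default_rng(5)
    for _ in range(10):
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        ours = mann_whitney_exact(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)


def test_kruskal_wallis_printed_value():
    """H on the published CSA groups is 10.82 (hand-ranked oracle)."""
    res = kruskal_wallis([LG_CSA, MG_CSA, SOL_CSA])
    assert res.statistic == pytest.approx(10.82, abs=0.01)
    ref = sps.kruskal(LG_CSA, MG_CSA, SOL_CSA)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)


def test_kruskal_wallis_degenerate_and_separated():
    res = kruskal_wallis([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    res = kruskal_wallis([[1.0, 2.0, 3.0], [100.0, 101.0, 102.0]])
    assert res.p_value < 0.05


def test_sample_size_reproduces_design():
    """d = 1.9, alpha = 0.05, power 0.90, one-tailed gives total n = 12."""
    assert sample_size_two_group_t(1.9, 0.05, 0.90, tails=1) == 12


def test_sample_size_floor_and_monotonicity():
    assert sample_size_two_group_t(100.0, 0.05, 0.90, tails=1) == 4
    ns = [sample_size_two_group_t(d, 0.05, 0.90, tails=1)
          for d in (0.5, 1.0, 1.9)]
    assert ns[0] >= ns[1] >= ns[2]


def test_power_monotone_in_n_and_d():
    for d in (0.5, 1.0, 1.9):
        p = [two_sample_t_power(d, n) for n in (3, 6, 12, 24)]
        assert np.all(np.diff(p) > 0)
    for n in (4, 8, 16):
        p = [two_sample_t_power(d, n) for d in (0.3, 0.8, 1.5, 2.5)]
        assert np.all(np.diff(p) > 0)


def test_sample_size_validation():
    with pytest.raises(ValueError):
        sample_size_two_group_t(-1.0)
    with pytest.raises(ValueError):
        sample_size_two_group_t(1.0, alpha=1.5)
    with pytest.raises(ValueError):
        sample_size_two_group_t(1.0, tails=3)
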