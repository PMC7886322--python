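"""Nonparametric group tests and the a priori power computation.

The Mann-Whitney U test is exact (full enumeration of rank arrangements)
for combined samples up to 20 observations, matching the convention of
standard statistical packages for small samples; the two-sided p-value is
twice the smaller tail, capped at 1.  The Kruskal-Wallis H statistic uses
mid-ranks with the tie correction.  Sample size for a two-group t-test is
computed with the noncentral t distribution, not the normal approximation.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "kruskal_wallis",
    "sample_size_two_group_t",
    "two_sample_t_power",
]

EXACT_LIMIT = 20  # combined n at or below which the exact test is used


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test with a stated significance threshold."""

    method: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.threshold


@lru_cache(maxsize=32)
def _comb_matrix(n_total: int, n_a: int) -> np.ndarray:
    """All C(n_total, n_a) index subsets as an int8 one-hot matrix."""
    combs = np.fromiter(
        (i for c in combinations(range(n_total), n_a) for i in c),
        dtype=np.int8,
    ).reshape(-1, n_a)
    onehot = np.zeros((len(combs), n_total), dtype=np.int8)
    np.put_along_axis(onehot, combs.astype(np.intp), 1, axis=1)
    return onehot


def rank_sum_null(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Permutation distribution of the group-a rank sum (handles ties)."""
    ranks = np.asarray(ranks, dtype=float)
    return _comb_matrix(len(ranks), n_a) @ ranks


def mann_whitney_exact(a, b, threshold: float = 0.05) -> TestResult:
    """Exact two-sided Mann-Whitney U test.

    For combined samples of at most ``EXACT_LIMIT`` observations the p-value
    is computed by full enumeration of the rank arrangements (mid-ranks, so
    ties are handled exactly in the permutation sense); larger samples use
    the normal approximation with tie correction.  The reported statistic is
    U = min(U_a, U_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = ranks[:n_a].sum()
    u_a = ra - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    if n_a + n_b <= EXACT_LIMIT:
        null = rank_sum_null(ranks, n_a)
        lo = np.mean(null <= ra + 1e-9)
        hi = np.mean(null >= ra - 1e-9)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "mann-whitney-exact"
    else:
        mean = n_a * n_b / 2.0
        n = n_a + n_b
        _, counts = np.unique(ranks, return_counts=True)
        tie = (counts**3 - counts).sum()
        var = n_a * n_b / 12.0 * ((n + 1) - tie / (n * (n - 1)))
        if var == 0:
            return TestResult("mann-whitney-normal", float(u), 1.0,
                              ("a", "b"), threshold)
        z = (u_a - mean) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "mann-whitney-normal"
    return TestResult(method, float(u), float(p), ("a", "b"), threshold)


def kruskal_wallis(groups, threshold: float = 0.05) -> TestResult:
    """Kruskal-Wallis H test on mid-ranks with tie correction.

    ``groups`` is a sequence of >= 2 value arrays (each with >= 2 values).
    If every observation is identical, H is 0 and p is 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two values")
    alldata = np.concatenate(groups)
    n = len(alldata)
    ranks = sps.rankdata(alldata)
    _, counts = np.unique(alldata, return_counts=True)
    if len(counts) == 1:
        return TestResult("kruskal-wallis", 0.0, 1.0,
                          tuple(str(i) for i in range(len(groups))), threshold)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset:offset + len(g)].sum()
        h += r * r / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h /= tie
    df = len(groups) - 1
    p = float(sps.chi2.sf(h, df))
    return TestResult("kruskal-wallis", float(h), p,
                      tuple(str(i) for i in range(len(groups))), threshold)


def two_sample_t_power(d: float, n_per_group: int, alpha: float = 0.05,
                       tails: int = 1) -> float:
    """Power of the two-sample t-test at effect size d (noncentral t)."""
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / tails, df)
    return float(sps.nct.sf(tcrit, df, ncp))


def sample_size_two_group_t(d: float, alpha: float = 0.05,
                            power: float = 0.90, tails: int = 1,
                            max_n: int = 10**6) -> int:
    """Smallest total sample size (equal groups) reaching the target power.

    Uses the noncentral t distribution: the smallest per-group n such that a
    two-sample t-test with noncentrality d*sqrt(n/2) and df = 2n - 2 attains
    the requested power; the return value is the total 2n.  The minimum
    per-group n is 2 (df >= 2).
    """
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    n = 2
    while n <= max_n:
        if two_sample_t_power(d, n, alpha, tails) >= power:
            return 2 * n
        n += 1
    raise ValueError(f"requested power unreachable within n <= {max_n}")
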