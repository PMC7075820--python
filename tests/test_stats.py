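"""Rank tests and descriptive statistics against hand values, enumeration
oracles, and scipy's independent implementations."""

import itertools

import numpy as np
import pytest
import scipy.stats as ss

from nichedist import chi_square, kruskal_wallis, mann_whitney_u, median_iqr
from nichedist.cohort_analysis import ContingencyTable, holm_correction


def u_by_pair_counting(x, y):
    """Definition-level U: count of (x_i > y_j) pairs, ties counting half."""
    x, y = np.asarray(x), np.asarray(y)
    return float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))


def exact_permutation_midp(x, y):
    """Two-sided permutation mid-p by enumerating all group labelings.

    Mid-p counts labelings strictly more extreme than the observed |U - mu|
    in full and exactly-as-extreme ones at half weight; it is the quantity a
    continuity-uncorrected normal approximation estimates.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    mu = len(x) * len(y) / 2
    obs = abs(u_by_pair_counting(x, y) - mu)
    hits = total = 0.0
    for comb in itertools.combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        dev = abs(u_by_pair_counting(pooled[sel], pooled[~sel]) - mu)
        if dev > obs + 1e-12:
            hits += 1.0
        elif dev > obs - 1e-12:
            hits += 0.5
        total += 1
    return hits / total


def test_median_iqr_examples():
    assert median_iqr([1, 2, 3, 4, 5]) == (3, 2, 4)
    assert median_iqr([1, 2, 3, 4]) == (2.5, 1.75, 3.25)
    assert median_iqr([7]) == (7, 7, 7)
    with pytest.raises(ValueError):
        median_iqr([])


def test_mwu_degenerate_ties():
    res = mann_whitney_u([5, 5, 5], [5, 5, 5])
    assert res.statistic == 4.5 and res.p_two_sided == 1.0


def test_mwu_hand_example():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    # z = -4.5 / sqrt(5.25), two-sided normal tail
    assert res.p_two_sided == pytest.approx(0.04963, abs=5e-4)


def test_mwu_u_sum_and_swap_symmetry(rng):
    for _ in range(50):
        n1, n2 = rng.integers(2, 10, size=2)
        x = rng.integers(0, 6, size=n1).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=n2).astype(float)
        a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert a.statistic + b.statistic == pytest.approx(n1 * n2, abs=1e-9)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)


def test_mwu_matches_pair_counting_and_exact_p(rng):
    """Mid-rank U equals the pair-counting definition for tied and untied
    samples; on untied samples the normal p tracks the exact permutation
    mid-p within 0.05 (heavy ties at tiny n make the pooled rank
    distribution too lumpy for a continuous approximation, so the p check
    is tie-free)."""
    for _ in range(30):
        n1 = int(rng.integers(4, 8))
        n2 = int(rng.integers(4, 8))
        tied = rng.random() < 0.5
        if tied:
            x = rng.integers(0, 4, size=n1).astype(float)
            y = rng.integers(0, 4, size=n2).astype(float)
        else:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
        res = mann_whitney_u(x, y)
        assert res.statistic == pytest.approx(u_by_pair_counting(x, y), abs=1e-9)
        if not tied:
            assert abs(res.p_two_sided - exact_permutation_midp(x, y)) <= 0.05


def test_mwu_matches_scipy_asymptotic(rng):
    for _ in range(20):
        x = rng.normal(size=rng.integers(5, 30))
        y = rng.normal(size=rng.integers(5, 30))
        ours = mann_whitney_u(x, y)
        ref = ss.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=False)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)


def test_kw_hand_example():
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32.0 / 7.0, abs=1e-9)  # 4.5714...
    assert res.df == 2


def test_kw_all_tied():
    res = kruskal_wallis([[3, 3], [3, 3, 3], [3]])
    assert res.statistic == 0.0 and res.p_two_sided == 1.0 and res.df == 2


def test_kw_two_groups_equals_squared_mwu_z(rng):
    for _ in range(25):
        x = rng.normal(size=rng.integers(3, 12))
        y = rng.normal(size=rng.integers(3, 12))  # continuous: no ties
        h = kruskal_wallis([x, y]).statistic
        u = mann_whitney_u(x, y)
        n1, n2 = len(x), len(y)
        var = n1 * n2 * (n1 + n2 + 1) / 12.0
        z = (u.statistic - n1 * n2 / 2.0) / np.sqrt(var)
        assert h == pytest.approx(z**2, abs=1e-9)


def test_kw_monotone_transform_invariance(rng):
    groups = [rng.normal(size=8), rng.normal(size=6), rng.normal(size=7)]
    base = kruskal_wallis(groups)
    warped = kruskal_wallis([np.exp(3 * g) for g in groups])
    assert base.statistic == pytest.approx(warped.statistic, abs=1e-9)


def test_kw_matches_scipy(rng):
    for _ in range(15):
        groups = [rng.integers(0, 8, size=rng.integers(5, 20)).astype(float) for _ in range(3)]
        ours = kruskal_wallis(groups)
        ref = ss.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)


def test_chi_square_examples():
    t = ContingencyTable(np.array([[10, 10], [10, 10]]), ["a", "b"], ["c", "d"])
    res = chi_square(t)
    assert res.statistic == 0.0 and res.df == 1 and res.p_two_sided == 1.0

    t = ContingencyTable(np.array([[20, 10], [10, 20]]), ["a", "b"], ["c", "d"])
    res = chi_square(t)
    assert res.statistic == pytest.approx(20.0 / 3.0, abs=1e-9)  # 6.6667
    assert res.df == 1

    t = ContingencyTable(np.ones((3, 5)), list("abc"), list("vwxyz"))
    assert chi_square(t).df == 8


def test_chi_square_permutation_invariance(rng):
    counts = rng.integers(1, 30, size=(3, 4))
    base = chi_square(ContingencyTable(counts, list("abc"), list("wxyz")))
    perm = counts[np.argsort(rng.random(3))][:, np.argsort(rng.random(4))]
    res = chi_square(ContingencyTable(perm, list("abc"), list("wxyz")))
    assert res.statistic == pytest.approx(base.statistic, abs=1e-9)


def test_chi_square_matches_scipy(rng):
    counts = rng.integers(1, 40, size=(2, 3))
    ours = chi_square(ContingencyTable(counts, ["a", "b"], ["x", "y", "z"]))
    stat, p, df, _ = ss.chi2_contingency(counts, correction=False)
    assert ours.statistic == pytest.approx(stat, abs=1e-9)
    assert ours.p_two_sided == pytest.approx(p, abs=1e-9)
    assert ours.df == df


def test_chi_square_zero_marginal():
    with pytest.raises(ValueError):
        chi_square(ContingencyTable(np.array([[0, 0], [5, 3]]), ["a", "b"], ["c", "d"]))


def test_errors_on_empty_inputs():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


def test_holm_correction_order():
    adj = holm_correction([0.01, 0.04, 0.03])
    assert adj[0] == pytest.approx(0.03)
    assert all(0 <= p <= 1 for p in adj)
    assert adj[1] >= 0.04
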