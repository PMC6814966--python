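"""Nonparametric tests against independent enumeration oracles."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy.special import comb
from scipy.stats import hypergeom, rankdata

from polyqppi.stats import (
    PairedSample,
    fisher_exact,
    mann_whitney,
    ols_fit,
    permutation_regression_compare,
    sign_test,
    sign_test_from_differences,
)


# ---------------------------------------------------------------- sign test

def enumerate_sign_test(diffs):
    """Oracle: exact p over all 2^n equally likely sign assignments."""
    nonzero = [d for d in diffs if d != 0]
    n = len(nonzero)
    if n == 0:
        return 1.0
    k_obs = sum(1 for d in nonzero if d > 0)
    obs_dev = abs(k_obs - n / 2)
    extreme = sum(
        1 for signs in product((1, -1), repeat=n)
        if abs(sum(s > 0 for s in signs) - n / 2) >= obs_dev
    )
    return extreme / 2**n


def test_sign_test_closed_forms():
    assert sign_test_from_differences([1] * 8) == (8, 0, 0, pytest.approx(2 * 0.5**8))
    assert sign_test_from_differences([1] * 5 + [-1] * 5)[3] == 1.0
    assert sign_test_from_differences([1, 1, 0, -1])[3] == 1.0  # n=3, k=2


def test_sign_test_all_ties():
    n_pos, n_neg, n_tie, p = sign_test_from_differences([0.0, 0.0])
    assert (n_pos, n_neg, n_tie, p) == (0, 0, 2, 1.0)


@pytest.mark.parametrize(
    "diffs",
    [
        [1, 1, 1, -1],
        [1, -1, 1, -1, 1, 1, 1, 0],
        [2, 3, -1, 4, 5, -2, 1, 1, 1, -3, 2, 2],
        [1] * 12,
        [-1, -1, 1],
    ],
)
def test_sign_test_matches_full_enumeration(diffs):
    _, _, _, p = sign_test_from_differences(diffs)
    assert p == pytest.approx(enumerate_sign_test(diffs), abs=1e-12)


def test_sign_test_paired_sample_interface():
    sample = PairedSample(labels=["a", "b", "c"], values_a=[1, 2, 3], values_b=[2, 3, 4])
    assert sign_test(sample) == (3, 0, 0, pytest.approx(0.25))
    with pytest.raises(ValueError):
        PairedSample(labels=["a", "a"], values_a=[1, 2], values_b=[1, 2])


# ------------------------------------------------------------- Mann-Whitney

def enumerate_mann_whitney(x, y):
    """Oracle: exact two-sided p over all group labelings of the pooled data."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_of(idx):
        ranks = rankdata(pooled)
        # U from rank sum of the chosen subset against the rest
        sub = np.zeros(len(pooled), bool)
        sub[list(idx)] = True
        r1 = rankdata(pooled)[sub].sum()
        return r1 - n * (n + 1) / 2

    mean_u = n * m / 2
    obs = abs(u_of(range(n)) - mean_u)
    total, extreme = 0, 0
    for idx in combinations(range(n + m), n):
        total += 1
        if abs(u_of(idx) - mean_u) >= obs - 1e-12:
            extreme += 1
    return extreme / total


def test_mann_whitney_complete_separation():
    u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0


def test_mann_whitney_identical_groups():
    _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
    assert p >= 0.99


@pytest.mark.parametrize(
    "x,y",
    [
        ([1, 3, 5], [2, 4]),
        ([1, 1, 2], [2, 3, 3]),
        ([10, 12, 14, 16], [11, 13, 15, 17, 19, 21]),
    ],
)
def test_mann_whitney_exact_matches_enumeration(x, y):
    _, p = mann_whitney(x, y)
    assert p == pytest.approx(enumerate_mann_whitney(np.array(x, float), np.array(y, float)), abs=1e-12)


def test_mann_whitney_large_samples_use_normal_approximation():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 40)
    y = rng.normal(0.8, 1, 40)
    _, p = mann_whitney(x, y)
    assert 0 < p < 0.05


def test_mann_whitney_empty_group_errors():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


# ------------------------------------------------------------ Fisher exact

def enumerate_fisher(table):
    """Oracle: sum hypergeometric pmf of all tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {k: hypergeom.pmf(k, n, col1, row1) for k in support}
    assert sum(pmf.values()) == pytest.approx(1.0, abs=1e-12)
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_closed_forms():
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
    assert fisher_exact([[5, 5], [5, 5]]) == 1.0


@pytest.mark.parametrize("table", [[[3, 1], [1, 3]], [[8, 2], [1, 5]], [[0, 5], [5, 0]]])
def test_fisher_matches_hypergeometric_enumeration(table):
    assert fisher_exact(table) == pytest.approx(enumerate_fisher(table), abs=1e-10)


def test_fisher_zero_margin():
    assert fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]])


# --------------------------------------------------------------------- OLS

def test_ols_exact_line():
    x = np.arange(10.0)
    fit = ols_fit(x, 2 * x + 1)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_ols_constant_y():
    fit = ols_fit([0, 1, 2, 3], [5, 5, 5, 5])
    assert fit.slope == 0.0
    assert fit.r_squared == 0.0


def test_ols_closed_form_three_points():
    fit = ols_fit([0, 1, 2], [1, 3, 4])
    assert fit.slope == pytest.approx(1.5)
    assert fit.intercept == pytest.approx(7 / 6)


def test_ols_constant_x_errors():
    with pytest.raises(ValueError):
        ols_fit([1, 1, 1], [1, 2, 3])


# ------------------------------------------------- permutation comparison

def _line_points(rng, n, slope, intercept, sd):
    x = rng.uniform(0, 10, n)
    return list(zip(x, slope * x + intercept + rng.normal(0, sd, n)))


def test_permutation_deterministic_for_fixed_seed():
    rng = np.random.default_rng(0)
    a = _line_points(rng, 15, 2.0, 1.0, 0.5)
    b = _line_points(rng, 12, 2.0, 1.0, 0.5)
    res1 = permutation_regression_compare(a, b, n_perm=200, seed=7)
    res2 = permutation_regression_compare(a, b, n_perm=200, seed=7)
    assert np.array_equal(res1[0].resampled_slopes, res2[0].resampled_slopes)
    assert res1[1].prop_intercept_ge == res2[1].prop_intercept_ge


def test_permutation_self_comparison_is_central():
    rng = np.random.default_rng(3)
    pts = _line_points(rng, 30, 3.0, 2.0, 1.0)
    res_a, res_b = permutation_regression_compare(pts, pts, n_perm=2000, seed=1)
    # each group IS a draw from the pool, so its slope sits mid-distribution
    for res in (res_a, res_b):
        assert 0.3 < res.prop_slope_ge < 0.7
        assert 0.3 < res.prop_slope_le < 0.7
        assert res.prop_slope_ge + res.prop_slope_le >= 1.0  # overlap at ties


def test_permutation_input_validation():
    pts = [(0, 0), (1, 1), (2, 2)]
    with pytest.raises(ValueError):
        permutation_regression_compare(pts[:2], pts, n_perm=10, seed=0)
    with pytest.raises(ValueError):
        permutation_regression_compare(pts, pts, n_perm=0, seed=0)


def test_permutation_result_vectors_have_length_n_perm():
    rng = np.random.default_rng(5)
    a = _line_points(rng, 10, 1.0, 0.0, 0.2)
    b = _line_points(rng, 8, 1.0, 0.0, 0.2)
    res_a, res_b = permutation_regression_compare(a, b, n_perm=123, seed=2)
    assert len(res_a.resampled_slopes) == 123
    assert len(res_b.resampled_intercepts) == 123
    for res in (res_a, res_b):
        for prop in (res.prop_slope_ge, res.prop_slope_le,
                     res.prop_intercept_ge, res.prop_intercept_le):
            assert 0.0 <= prop <= 1.0
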