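"""Nonparametric statistics for the variant comparison.

Exact paired sign test, Mann–Whitney U (exact enumeration for small
samples, tie-corrected normal approximation otherwise), Fisher's exact
test, ordinary least squares, and an empirical comparison of two
regression lines by pooled subset resampling: all points are pooled,
random subsets of each group's size are drawn without replacement, a line
is fit to each draw, and the observed slope/intercept of each group is
located within the resampled distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSample",
    "RegressionResult",
    "PermutationResult",
    "sign_test",
    "sign_test_from_differences",
    "mann_whitney",
    "fisher_exact",
    "ols_fit",
    "permutation_regression_compare",
    "DEFAULT_SEED",
]

#: Default RNG seed for the stochastic operations.
DEFAULT_SEED = 20191026

#: Exact Mann-Whitney enumeration is attempted when min(n, m) is below this.
MW_EXACT_MIN_GROUP = 8
#: ... and the number of labelings does not exceed this.
MW_MAX_ENUMERATION = 200_000


@dataclass
class PairedSample:
    """Per-interactor paired metric values (e.g. wt vs expanded)."""

    labels: list[str]
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("paired-sample labels must be unique")
        if not (len(self.labels) == len(self.values_a) == len(self.values_b)) or len(self.labels) < 1:
            raise ValueError("labels/values_a/values_b must have equal length >= 1")


def sign_test_from_differences(diffs: Sequence[float]) -> tuple[int, int, int, float]:
    """Exact two-sided sign test on a vector of paired differences.

    Ties (zero differences) are dropped; p doubles the smaller binomial
    tail at theta = 1/2, capped at 1.  Returns (n_pos, n_neg, n_tie, p).
    """
    diffs = np.asarray(diffs, dtype=float)
    n_pos = int(np.sum(diffs > 0))
    n_neg = int(np.sum(diffs < 0))
    n_tie = int(np.sum(diffs == 0))
    n = n_pos + n_neg
    if n == 0:
        logger.info("sign test: all %d pairs tied; p = 1", n_tie)
        return n_pos, n_neg, n_tie, 1.0
    k = min(n_pos, n_neg)
    p = min(1.0, 2.0 * float(sps.binom.cdf(k, n, 0.5)))
    return n_pos, n_neg, n_tie, p


def sign_test(sample: PairedSample) -> tuple[int, int, int, float]:
    """Exact paired sign test of values_b against values_a."""
    return sign_test_from_differences(sample.values_b - sample.values_a)


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x from midrank sums."""
    n, m = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n].sum()
    return float(r1 - n * (n + 1) / 2.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_min_group: int = MW_EXACT_MIN_GROUP,
) -> tuple[float, float]:
    """Mann–Whitney U test, two-sided.

    The U statistic of ``x`` comes from midrank sums.  For
    min(n, m) >= ``exact_min_group`` the p-value is the tie-corrected
    normal approximation with continuity correction; below that, exact
    enumeration over all group labelings (two-sided by distance of U from
    its mean, which remains well-defined under ties).  Enumeration falls
    back to the approximation if the number of labelings is impractically
    large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n, m = len(x), len(y)
    u = _mw_u(x, y)

    if min(n, m) < exact_min_group and math.comb(n + m, n) <= MW_MAX_ENUMERATION:
        pooled = np.concatenate([x, y])
        mean_u = n * m / 2.0
        obs_dev = abs(u - mean_u)
        total = 0
        extreme = 0
        idx_all = frozenset(range(n + m))
        for combo in combinations(range(n + m), n):
            xs = pooled[list(combo)]
            ys = pooled[list(idx_all - set(combo))]
            total += 1
            if abs(_mw_u(xs, ys) - mean_u) >= obs_dev - 1e-12:
                extreme += 1
        return u, extreme / total

    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return u, float(res.pvalue)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p on a 2x2 count table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one.  A zero margin gives
    p = 1 with a logged note.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.info("fisher_exact: zero margin; p = 1")
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line fit; r² = 1 − SSE/SST (0 when y is constant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length x, y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n=len(x),
    )


@dataclass
class PermutationResult:
    """Location of one group's fitted line within the pooled resampling null."""

    n_perm: int
    seed: int
    observed: RegressionResult
    prop_slope_ge: float
    prop_slope_le: float
    prop_intercept_ge: float
    prop_intercept_le: float
    resampled_slopes: np.ndarray
    resampled_intercepts: np.ndarray


def _resample_lines(
    x: np.ndarray, y: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS over ``n_perm`` random subsets of ``size`` points."""
    n = len(x)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
    xs = x[idx]
    ys = y[idx]
    mx = xs.mean(axis=1)
    my = ys.mean(axis=1)
    cov = (xs * ys).mean(axis=1) - mx * my
    var = (xs * xs).mean(axis=1) - mx * mx
    slopes = cov / var
    intercepts = my - slopes * mx
    return slopes, intercepts


def permutation_regression_compare(
    points_a: Sequence[tuple[float, float]],
    points_b: Sequence[tuple[float, float]],
    n_perm: int = 1000,
    seed: int = DEFAULT_SEED,
) -> tuple[PermutationResult, PermutationResult]:
    """Compare two fitted regression lines against a pooled resampling null.

    All points are pooled; for each of ``n_perm`` draws a subset of size
    |a| is sampled without replacement and a line fitted, locating group
    a's observed slope and intercept within the resampled distributions;
    the same is done symmetrically for |b| against group b's line.  One
    resample stream yields both the slope and intercept proportions of a
    draw.  Fully determined by ``seed``.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("points must be sequences of (x, y) pairs")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 points")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    pool_x = np.concatenate([a[:, 0], b[:, 0]])
    pool_y = np.concatenate([a[:, 1], b[:, 1]])
    rng = np.random.default_rng(seed)

    results = []
    for group in (a, b):
        observed = ols_fit(group[:, 0], group[:, 1])
        slopes, intercepts = _resample_lines(pool_x, pool_y, len(group), n_perm, rng)
        results.append(
            PermutationResult(
                n_perm=n_perm,
                seed=seed,
                observed=observed,
                prop_slope_ge=float(np.mean(slopes >= observed.slope)),
                prop_slope_le=float(np.mean(slopes <= observed.slope)),
                prop_intercept_ge=float(np.mean(intercepts >= observed.intercept)),
                prop_intercept_le=float(np.mean(intercepts <= observed.intercept)),
                resampled_slopes=slopes,
                resampled_intercepts=intercepts,
            )
        )
    return results[0], results[1]
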