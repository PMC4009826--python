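"""Replicative-lifespan analysis from pedigree division counts.

Pedigree dissection follows every mother cell to death, so the survival
data are complete (no censoring): the survivor function at age ``a`` is
simply the fraction of mothers with more than ``a`` completed divisions,
and the median lifespan the smallest age at which it drops to 50 % or
below.  Groups are compared with Gehan's generalized Wilcoxon test (the
Gehan-Breslow-Wilcoxon test), which weights early deaths by the number of
mothers still at risk; with complete data Gehan's pairwise score for
observation ``i`` reduces to

    h_i = #{j : x_i > x_j} - #{j : x_i < x_j}

over the pooled sample (ties score 0), the statistic is the sum of scores
in one group, and its null variance is the exact permutation variance
m n / (N (N - 1)) * sum(h_i^2).  A label-permutation p-value (with the
add-one estimator, so p is never 0) is available alongside the chi-square
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .simkit import PedigreeSample

__all__ = [
    "SurvivalCurve",
    "LifespanTest",
    "survival_curve",
    "median_lifespan",
    "gehan_breslow_wilcoxon",
    "gehan_scores",
]


@dataclass
class SurvivalCurve:
    """Fraction of mothers alive after each number of divisions."""

    divisions: np.ndarray  # integer ages 0..max
    surviving_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.divisions = np.asarray(self.divisions, dtype=int)
        self.surviving_fraction = np.asarray(self.surviving_fraction, dtype=float)


@dataclass
class LifespanTest:
    statistic: float  # Gehan-Breslow-Wilcoxon chi-square
    p_value: float
    method: str  # 'normal_approximation' | 'permutation'
    score_sum: float  # sum of Gehan scores in group A
    n_a: int
    n_b: int


def survival_curve(pedigree: PedigreeSample) -> SurvivalCurve:
    """Step survivor function S(a) = #{divisions > a} / n for a = 0..max."""
    d = pedigree.divisions
    if d.size == 0:
        raise ValueError("empty pedigree")
    ages = np.arange(d.max() + 1)
    surviving = np.array([(d > a).mean() for a in ages])
    return SurvivalCurve(divisions=ages, surviving_fraction=surviving)


def median_lifespan(pedigree: PedigreeSample) -> int:
    """Smallest division count at which half or fewer mothers survive."""
    curve = survival_curve(pedigree)
    idx = np.nonzero(curve.surviving_fraction <= 0.5)[0]
    return int(curve.divisions[idx[0]])


def gehan_scores(pooled: np.ndarray) -> np.ndarray:
    """Gehan score of each pooled observation: #{smaller} - #{larger}."""
    pooled = np.asarray(pooled, dtype=float)
    order = np.argsort(pooled, kind="mergesort")
    sorted_vals = pooled[order]
    # counts strictly below / strictly above via searchsorted on sorted copy
    below = np.searchsorted(sorted_vals, pooled, side="left")
    above = pooled.size - np.searchsorted(sorted_vals, pooled, side="right")
    return (below - above).astype(float)


def gehan_breslow_wilcoxon(
    group_a: PedigreeSample | np.ndarray,
    group_b: PedigreeSample | np.ndarray,
    method: str = "normal_approximation",
    n_permutations: int = 10000,
    seed: int = 0,
) -> LifespanTest:
    """Gehan's generalized Wilcoxon comparison of two complete lifespan samples.

    ``method='normal_approximation'`` refers the chi-square
    W^2 / Var(W) (permutation variance) to chi2(1);
    ``method='permutation'`` shuffles group labels ``n_permutations`` times
    and reports the two-sided add-one p-value (b+1)/(B+1).
    """
    a = group_a.divisions if isinstance(group_a, PedigreeSample) else np.asarray(group_a)
    b = group_b.divisions if isinstance(group_b, PedigreeSample) else np.asarray(group_b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each group needs at least 5 mothers")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all values tied across both groups")
    h = gehan_scores(pooled)
    m, n = a.size, b.size
    N = m + n
    W = float(h[:m].sum())
    var = m * n / (N * (N - 1.0)) * float(np.sum(h**2))
    chi2 = W**2 / var if var > 0 else 0.0

    if method == "normal_approximation":
        p = float(sps.chi2.sf(chi2, df=1))
        # chi2.sf can return exactly 0 only by underflow; clamp into (0, 1]
        p = min(max(p, np.finfo(float).tiny), 1.0)
    elif method == "permutation":
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_permutations, N)), axis=1)[:, :m]
        w_perm = h[idx].sum(axis=1)
        hits = int(np.sum(np.abs(w_perm) >= abs(W) - 1e-12))
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError("method must be 'normal_approximation' or 'permutation'")

    return LifespanTest(
        statistic=chi2, p_value=float(p), method=method, score_sum=W, n_a=m, n_b=n
    )
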