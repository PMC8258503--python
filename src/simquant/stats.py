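"""Self-contained statistics used by the batch pipelines: simple linear
regression with R-squared, the Mann-Whitney U test, and Spearman rank
correlation.

These are implemented directly (closed forms plus exact permutation
enumeration) rather than delegated, so the phantom-based validation runs
are self-contained and each routine can be checked against independent
oracles.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RegressionFit",
    "MWUResult",
    "linear_regression",
    "mann_whitney",
    "spearman_rho",
]

#: Largest combined sample size for which the exact permutation null of the
#: Mann-Whitney U is enumerated; beyond it the tie-corrected normal
#: approximation is used.
EXACT_MWU_LIMIT = 16


@dataclasses.dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares line y = slope*x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclasses.dataclass(frozen=True)
class MWUResult:
    """Mann-Whitney U (reported for the first group) and two-sided p."""

    u_statistic: float
    p_two_sided: float
    method: Literal["exact", "normal-approximation"]


def _mid_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based; ties share the average of their rank block)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares fit with R-squared = squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("linear regression requires n >= 3")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("x is constant: slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    r_squared = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return RegressionFit(slope=slope, intercept=intercept, r_squared=r_squared, n=n)


def _u_from_ranks(rank_sum_a: float, n1: int) -> float:
    return rank_sum_a - n1 * (n1 + 1) / 2.0


def _exact_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """P(|U - mu| >= |u_obs - mu|) under random assignment of the pooled
    (mid-)ranks to group sizes (n1, n-n1); full enumeration."""
    n = len(pooled_ranks)
    mu = n1 * (n - n1) / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = _u_from_ranks(sum(pooled_ranks[i] for i in combo), n1)
        hits += abs(u - mu) >= dev
        total += 1
    return hits / total


def _normal_p(pooled_ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction;
    two-sided p doubles the smaller tail, capped at 1."""
    n = len(pooled_ranks)
    n2 = n - n1
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    method: Literal["auto", "exact", "normal"] = "auto",
) -> MWUResult:
    """Two-sided Mann-Whitney U test; U is reported for group ``a``.

    The exact permutation null is enumerated when the combined sample size
    is at most ``EXACT_MWU_LIMIT`` (ties handled via mid-rank permutation);
    larger samples use the tie-corrected normal approximation with
    continuity correction. ``method`` overrides the automatic choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = _mid_ranks(pooled)
    n1 = len(a)
    u_obs = _u_from_ranks(float(ranks[:n1].sum()), n1)
    if method == "auto":
        method = "exact" if len(pooled) <= EXACT_MWU_LIMIT else "normal"
    if method == "exact":
        if math.comb(len(pooled), n1) > 5_000_000:
            raise ValueError(
                "exact enumeration infeasible for these group sizes; "
                "use method='normal' or 'auto'"
            )
        p = _exact_p(ranks, n1, u_obs)
        return MWUResult(u_statistic=u_obs, p_two_sided=p, method="exact")
    p = _normal_p(ranks, n1, u_obs)
    return MWUResult(u_statistic=u_obs, p_two_sided=p, method="normal-approximation")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("spearman_rho requires equal-length 1-D sequences, n >= 3")
    rx = _mid_ranks(x)
    ry = _mid_ranks(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(np.sum(sx**2)) * float(np.sum(sy**2)))
    if denom == 0:
        raise ValueError("spearman_rho undefined for constant input")
    return float(np.sum(sx * sy) / denom)
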