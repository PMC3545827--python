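"""Inter-responder rank concordance via Spearman's ρ.

Two responders agree to the extent that they rank the same items in the
same order; Spearman's ρ is the Pearson correlation of the two rank
vectors, with tied weights receiving their average (mid) rank.  Mid-rank
handling is essential here: elicited weight profiles routinely contain
exact ties (e.g. a responder judging all needs of one category equally).

Significance is tested two-sided against the null of no association.  For
short profiles (n ≤ 8 items) the permutation distribution of ρ is exact
and cheap to enumerate — all n! rank orderings of one vector — so the
exact p-value is used; for longer profiles the usual t approximation
t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PriorityProfile",
    "ConcordanceResult",
    "ConstantProfileError",
    "spearman_rho",
    "spearman_pvalue",
    "concordance_matrix",
    "EXACT_ENUMERATION_MAX_N",
]

#: Largest profile length for which the exact permutation null is enumerated.
EXACT_ENUMERATION_MAX_N = 8


class ConstantProfileError(ValueError):
    """All weights equal: rank correlation is undefined, not zero."""


@dataclass(frozen=True)
class PriorityProfile:
    """One responder's weights over a shared, ordered item list."""

    responder_id: str
    item_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.item_ids),):
            raise ValueError("weights length does not match item list")


@dataclass(frozen=True)
class ConcordanceResult:
    responder_ids: tuple[str, ...]
    item_ids: tuple[str, ...]
    rho: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray  # boolean mask, p < alpha
    alpha: float


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank tie handling.

    Ranks are assigned ascending (largest weight gets the largest rank);
    ties share the average of the ranks they span.  ρ is the Pearson
    correlation of the two rank vectors.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 items to rank")
    rx, ry = _ranks(xa), _ranks(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ConstantProfileError(
            "rank correlation is undefined for a constant profile"
        )
    # identical / exactly reversed rankings are ±1 by definition; bypass
    # corrcoef round-off so perfect concordance compares equal to 1.0
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx + ry, np.full_like(rx, len(rx) + 1)):
        return -1.0
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return min(1.0, max(-1.0, rho))


@lru_cache(maxsize=8)
def _perm_rho_distribution(n: int) -> np.ndarray:
    """|ρ| of every permutation of ranks 1..n against the identity order."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(permutations(range(n))), dtype=float) + 1.0
    bc = base - base.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((bc @ bc) * (pc * pc).sum(axis=1))
    return np.abs(pc @ bc) / denom


def spearman_pvalue(rho: float, n: int, two_sided: bool = True) -> float:
    """P-value for an observed ρ over ``n`` items.

    For n ≤ 8 the exact permutation null is enumerated: the p-value is the
    fraction of the n! rank orderings whose |ρ| meets or exceeds |ρ|
    observed (two-sided).  For larger n the t approximation is used; at
    |ρ| = 1, where the t statistic diverges, the exact enumeration bound
    2/n! is returned instead of 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 - 1e-12 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"rho={rho} outside [-1, 1]")
    rho = min(1.0, max(-1.0, rho))
    if n <= EXACT_ENUMERATION_MAX_N:
        dist = _perm_rho_distribution(n)
        p = float(np.mean(dist >= abs(rho) - 1e-12))
        return p if two_sided else p / 2.0
    if abs(rho) >= 1.0 - 1e-15:
        import math
        p = 2.0 / math.factorial(n)
        return p if two_sided else p / 2.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return p if two_sided else p / 2.0


def concordance_matrix(
    profiles: Sequence[PriorityProfile],
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Pairwise ρ and p over all responders sharing one item list.

    The full matrix is always computed and reported together with the
    significance mask at ``alpha``; non-significant entries are never
    suppressed.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to compare")
    items = profiles[0].item_ids
    for p in profiles[1:]:
        if p.item_ids != items:
            raise ValueError(
                f"profile {p.responder_id!r} has a different item list"
            )
    m = len(profiles)
    n = len(items)
    rho = np.eye(m)
    pval = np.full((m, m), spearman_pvalue(1.0, n))  # diagonal: self ρ = 1
    for i in range(m):
        for j in range(i + 1, m):
            r = spearman_rho(profiles[i].weights, profiles[j].weights)
            p = spearman_pvalue(r, n)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    mask = pval < alpha
    return ConcordanceResult(
        responder_ids=tuple(p.responder_id for p in profiles),
        item_ids=items, rho=rho, pvalues=pval, significant=mask, alpha=alpha,
    )
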