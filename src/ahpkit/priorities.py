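"""Priority vectors, consistency screening, hierarchical aggregation.

Local weights come from the principal (Perron) eigenvector of a node's
judgment matrix.  For a perfectly transitive matrix every column is already
proportional to the weight vector and the dominant eigenvalue λ_max equals
the dimension n; real responders are never perfectly transitive, and the
excess λ_max − n measures how far they stray.  The consistency index
CI = (λ_max − n)/(n − 1), divided by the expected CI of random matrices of
the same size (the tabulated Random Index), gives the consistency ratio CR.
Judgment sets with CR ≤ 0.1 are conventionally acceptable; 0.2 is a relaxed
bound used when re-elicitation is impractical.

Global weights multiply each need's local weight by its category's weight
at the goal, so the twelve-or-so leaf weights again sum to one (distributive
mode) and can be ranked against each other across categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .elicitation import JudgmentMatrix

__all__ = [
    "PriorityResult",
    "ConsistencyReport",
    "GlobalPriorities",
    "RankedNeed",
    "principal_priorities",
    "consistency_report",
    "random_index",
    "global_weights",
    "rank_needs",
    "RANDOM_INDEX",
]

#: Tabulated Random Index: expected CI of random reciprocal matrices,
#: indexed by matrix dimension n = 1 … 9.  n ≤ 2 matrices are always
#: consistent, so their RI is 0.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45,
}


@dataclass(frozen=True)
class PriorityResult:
    """Normalized weights and dominant eigenvalue for one node."""

    node_id: str
    elements: tuple[str, ...]
    weights: np.ndarray
    lambda_max: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.elements, self.weights.tolist()))


@dataclass(frozen=True)
class ConsistencyReport:
    node_id: str
    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passes_primary: bool
    passes_relaxed: bool


@dataclass(frozen=True)
class GlobalPriorities:
    """Per-responder weight maps at every level of the hierarchy."""

    responder_id: str
    category_weights: dict[str, float]  # CW per category
    local_weights: dict[str, float]     # LW per need, within its category
    global_weights: dict[str, float]    # GW = LW × CW per need
    category_of: dict[str, str]         # need → its category


@dataclass(frozen=True)
class RankedNeed:
    need_id: str
    global_weight: float
    tied: bool


def principal_priorities(
    matrix: JudgmentMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PriorityResult:
    """Dominant-eigenvector weights of a judgment matrix (distributive mode).

    Power iteration on the positive matrix: Perron–Frobenius guarantees a
    unique dominant eigenvalue with a strictly positive eigenvector, so the
    iteration converges from the uniform start without deflation.  The
    vector is normalized to sum 1 at every step; convergence is declared
    when successive iterates differ by less than ``tol`` in max norm.
    λ_max is read off at convergence as Σ(Aw) for Σw = 1.
    """
    a = matrix.values
    n = matrix.n
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = a @ w
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - w)) < tol:
            w = nxt
            break
        w = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations "
            f"for node {matrix.node_id!r}"
        )
    lam = float((a @ w).sum())
    return PriorityResult(node_id=matrix.node_id, elements=matrix.elements,
                          weights=w, lambda_max=lam)


def random_index(n: int, table: Mapping[int, float] | None = None) -> float:
    """Tabulated Random Index for dimension ``n`` (1 ≤ n ≤ 9 by default).

    Pass a custom ``table`` for larger matrices or alternative RI estimates.
    """
    table = RANDOM_INDEX if table is None else table
    try:
        return table[n]
    except KeyError:
        raise ValueError(
            f"no Random Index tabulated for n={n}; supply a custom table "
            "covering this dimension"
        ) from None


def consistency_report(
    matrix: JudgmentMatrix,
    primary_threshold: float = 0.1,
    relaxed_threshold: float = 0.2,
    ri_table: Mapping[int, float] | None = None,
) -> ConsistencyReport:
    """CI, RI and CR for one judgment matrix, with pass flags.

    CI = (λ_max − n)/(n − 1); CR = CI/RI(n).  For n ≤ 2 a reciprocal matrix
    is always consistent, so CR is defined as 0.  A tiny negative CI from
    floating-point round-off is floored at 0.
    """
    pr = principal_priorities(matrix)
    n = matrix.n
    ci = 0.0 if n <= 1 else (pr.lambda_max - n) / (n - 1)
    ci = max(ci, 0.0) if ci > -1e-12 else ci
    if ci < 0:
        raise AssertionError(f"negative CI {ci} for node {matrix.node_id!r}")
    ri = random_index(n, ri_table)
    cr = 0.0 if n <= 2 else ci / ri
    return ConsistencyReport(
        node_id=matrix.node_id, n=n, lambda_max=pr.lambda_max,
        ci=ci, ri=ri, cr=cr,
        passes_primary=cr <= primary_threshold,
        passes_relaxed=cr <= relaxed_threshold,
    )


def global_weights(
    category_priorities: PriorityResult,
    local_priorities: Sequence[PriorityResult],
    responder_id: str = "",
) -> GlobalPriorities:
    """Aggregate local weights into global need weights: GW = LW × CW.

    ``category_priorities`` holds the category weights at the goal node;
    ``local_priorities`` holds one result per category, whose ``node_id``
    must match a category element.  Because category weights sum to 1 and
    each category's local weights sum to 1, the global weights sum to 1.
    """
    by_cat = {pr.node_id: pr for pr in local_priorities}
    cats = category_priorities.elements
    missing = [c for c in cats if c not in by_cat]
    if missing:
        raise ValueError(f"missing local priorities for categories: {missing}")
    extra = [c for c in by_cat if c not in cats]
    if extra:
        raise ValueError(f"local priorities for unknown categories: {extra}")

    cw = category_priorities.as_dict()
    lw: dict[str, float] = {}
    gw: dict[str, float] = {}
    cat_of: dict[str, str] = {}
    for cat in cats:
        for need, w in by_cat[cat].as_dict().items():
            if need in lw:
                raise ValueError(f"need {need!r} appears in two categories")
            lw[need] = w
            gw[need] = w * cw[cat]
            cat_of[need] = cat
    return GlobalPriorities(
        responder_id=responder_id, category_weights=cw,
        local_weights=lw, global_weights=gw, category_of=cat_of,
    )


def rank_needs(gp: GlobalPriorities, k: int | None = None,
               tie_tol: float = 1e-12) -> list[RankedNeed]:
    """Needs sorted by global weight, descending.

    Ties (equal weights within ``tie_tol``) keep hierarchy order — the
    insertion order of ``gp.global_weights`` — and are flagged.
    """
    items = list(gp.global_weights.items())
    if k is None:
        k = len(items)
    if k > len(items):
        raise ValueError(f"k={k} exceeds the number of needs ({len(items)})")
    # stable sort preserves hierarchy order among equals
    ordered = sorted(items, key=lambda kv: -kv[1])
    out: list[RankedNeed] = []
    for i, (need, w) in enumerate(ordered[:k]):
        tied = (i > 0 and abs(ordered[i - 1][1] - w) <= tie_tol) or (
            i + 1 < len(ordered) and abs(ordered[i + 1][1] - w) <= tie_tol
        )
        out.append(RankedNeed(need_id=need, global_weight=w, tied=tied))
    return out
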