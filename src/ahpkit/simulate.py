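"""Synthetic responders with known latent priorities.

Each simulated responder carries a latent weight simplex for the categories
and one per category for its needs, drawn from a symmetric Dirichlet
(concentration 1 = uniform on the simplex; larger concentrations pull
profiles toward equality, smaller ones toward sharply peaked priorities
like a real emergency clinician's safety-dominated profile).

A responder's judgment for pair (i, j) starts from the true ratio w_i/w_j —
exactly the transitive construction, so a noiseless matrix has CR = 0 — and
is perturbed multiplicatively: a_ij = (w_i/w_j)·exp(ε) with ε ~ N(0, σ²)
applied to the upper triangle only, the lower triangle forced reciprocal.
Log-space noise keeps the matrix positive and reciprocal at any σ.  With
quantization on, each perturbed ratio is snapped to the nearest response
grid value in log space, emulating the verbal scale's coarseness; snapping
in log space makes reciprocal pairs snap consistently.

What this emulates — and does not: it produces responders whose
inconsistency is tunable, symmetric noise on top of a coherent latent
preference.  Real responders also exhibit order effects, fatigue and
deliberate intransitivity, none of which are modeled; recovery results here
bound what the pipeline can do under well-behaved noise only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .elicitation import (
    DEFAULT_SCALE,
    ComparisonSchedule,
    JudgmentMatrix,
    JudgmentScale,
    ResponseSet,
    build_schedule,
)
from .hierarchy import Hierarchy
from .priorities import GlobalPriorities

__all__ = [
    "LatentProfile",
    "SimulationConfig",
    "SyntheticStudy",
    "RecoveryMetrics",
    "sample_latent_profile",
    "judgments_from_profile",
    "responses_from_matrix",
    "simulate_study",
    "recovery_report",
]


@dataclass(frozen=True)
class LatentProfile:
    """Ground-truth priorities for one simulated responder."""

    responder_id: str
    category_weights: dict[str, float]
    local_weights: dict[str, dict[str, float]]  # category → need → LW

    @property
    def global_weights(self) -> dict[str, float]:
        gw: dict[str, float] = {}
        for cat, cw in self.category_weights.items():
            for need, lw in self.local_weights[cat].items():
                gw[need] = lw * cw
        return gw

    def node_weights(self, h: Hierarchy, node_id: str) -> dict[str, float]:
        if node_id == h.goal_id:
            return self.category_weights
        return self.local_weights[node_id]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation settings.

    ``noise`` is the log-scale σ of the multiplicative judgment
    perturbation (0 = perfectly transitive responders); ``concentration``
    is the symmetric Dirichlet parameter for latent weights.  A fixed seed
    makes the whole study byte-reproducible, and each (responder, node)
    pair derives its own substream so any single responder can be
    regenerated in isolation.
    """

    hierarchy: Hierarchy
    n_responders: int = 5
    concentration: float = 1.0
    noise: float = 0.0
    quantize: bool = True
    seed: int = 0
    scale: JudgmentScale = field(default=DEFAULT_SCALE)

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise (sigma) must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_responders < 1:
            raise ValueError("need at least one responder")


def _node_stream(seed: int, responder_index: int, node_id: str,
                 purpose: int) -> np.random.Generator:
    # stable 32-bit digest of the node id keeps streams independent per node
    digest = int.from_bytes(hashlib.sha256(node_id.encode()).digest()[:4], "big")
    return np.random.default_rng([seed, responder_index, digest, purpose])


def sample_latent_profile(cfg: SimulationConfig, responder_index: int) -> LatentProfile:
    """Draw one responder's latent simplexes, deterministically under seed."""
    h = cfg.hierarchy
    rid = f"resp{responder_index:03d}"
    rng = _node_stream(cfg.seed, responder_index, h.goal_id, purpose=0)
    cw = rng.dirichlet([cfg.concentration] * len(h.category_ids))
    lws: dict[str, dict[str, float]] = {}
    for cat in h.category_ids:
        rng_c = _node_stream(cfg.seed, responder_index, cat, purpose=0)
        needs = h.children_of(cat)
        lw = rng_c.dirichlet([cfg.concentration] * len(needs))
        lws[cat] = dict(zip(needs, lw.tolist()))
    return LatentProfile(
        responder_id=rid,
        category_weights=dict(zip(h.category_ids, cw.tolist())),
        local_weights=lws,
    )


def judgments_from_profile(
    profile: LatentProfile,
    hierarchy: Hierarchy,
    node_id: str,
    sigma: float = 0.0,
    quantize: bool = True,
    scale: JudgmentScale = DEFAULT_SCALE,
    rng: np.random.Generator | None = None,
) -> JudgmentMatrix:
    """Perturbed (optionally quantized) judgment matrix for one node.

    σ = 0 without quantization reproduces the exact ratio matrix
    a_ij = w_i/w_j, which is transitive by construction.
    """
    weights = profile.node_weights(hierarchy, node_id)
    elements = tuple(weights)
    w = np.array([weights[e] for e in elements], float)
    n = len(elements)
    if rng is None:
        rng = np.random.default_rng(0)
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ratio = w[i] / w[j]
            if sigma > 0:
                ratio *= float(np.exp(rng.normal(0.0, sigma)))
            if quantize:
                ratio = scale.snap(ratio)
            a[i, j] = ratio
            a[j, i] = 1.0 / ratio
    return JudgmentMatrix(node_id=node_id, elements=elements, values=a)


def responses_from_matrix(
    matrix: JudgmentMatrix,
    schedule: ComparisonSchedule,
    responder_id: str,
    scale: JudgmentScale = DEFAULT_SCALE,
) -> ResponseSet:
    """Verbal grades a responder holding ``matrix`` would give.

    Each scheduled ratio is mapped to its nearest grade; for a quantized
    matrix the mapping is exact and the round trip back to a matrix is the
    identity.
    """
    idx = {e: i for i, e in enumerate(matrix.elements)}
    grades = {
        (l, r): scale.nearest_grade(matrix.values[idx[l], idx[r]])
        for l, r in schedule.pairs
    }
    return ResponseSet(responder_id=responder_id, node_id=matrix.node_id,
                       grades=grades)


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete simulated study with its ground truth attached."""

    config: SimulationConfig
    profiles: list[LatentProfile]
    matrices: dict[str, dict[str, JudgmentMatrix]]  # responder → node → matrix
    response_sets: dict[str, dict[str, ResponseSet]]

    def responses_frame(self):
        """All graded answers as a tidy table (responses-CSV layout)."""
        import pandas as pd

        rows = []
        for rid, per_node in self.response_sets.items():
            for node_id, rs in per_node.items():
                for (l, r), g in rs.grades.items():
                    rows.append({"responder_id": rid, "node_id": node_id,
                                 "left_id": l, "right_id": r, "grade": g})
        return pd.DataFrame(rows)

    def truth_payload(self) -> dict:
        """Latent profiles + settings, for a truth.json sidecar."""
        return {
            "seed": self.config.seed,
            "noise": self.config.noise,
            "concentration": self.config.concentration,
            "quantize": self.config.quantize,
            "profiles": [
                {
                    "responder_id": p.responder_id,
                    "category_weights": p.category_weights,
                    "local_weights": p.local_weights,
                    "global_weights": p.global_weights,
                }
                for p in self.profiles
            ],
        }


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Simulate every responder answering every node's questionnaire.

    Judgment matrices are always produced; verbal response sets are graded
    off the matrices (an exact encoding when quantization is on).
    """
    h = cfg.hierarchy
    profiles = [sample_latent_profile(cfg, i) for i in range(cfg.n_responders)]
    matrices: dict[str, dict[str, JudgmentMatrix]] = {}
    responses: dict[str, dict[str, ResponseSet]] = {}
    for i, prof in enumerate(profiles):
        per_node_m: dict[str, JudgmentMatrix] = {}
        per_node_r: dict[str, ResponseSet] = {}
        for node_id, children in h.comparison_nodes():
            rng = _node_stream(cfg.seed, i, node_id, purpose=1)
            m = judgments_from_profile(
                prof, h, node_id, sigma=cfg.noise,
                quantize=cfg.quantize, scale=cfg.scale, rng=rng,
            )
            per_node_m[node_id] = m
            sched = build_schedule(node_id, children)
            per_node_r[node_id] = responses_from_matrix(
                m, sched, prof.responder_id, cfg.scale
            )
        matrices[prof.responder_id] = per_node_m
        responses[prof.responder_id] = per_node_r
    return SyntheticStudy(config=cfg, profiles=profiles,
                          matrices=matrices, response_sets=responses)


@dataclass(frozen=True)
class RecoveryMetrics:
    responder_id: str
    l1_distance: float
    spearman_rho: float
    top_k_overlap: int
    k: int


def recovery_report(
    truths: list[LatentProfile],
    recovered: list[GlobalPriorities],
    k: int = 5,
) -> list[RecoveryMetrics]:
    """Compare recovered global weights against the latent ground truth.

    Per responder: L1 distance between the weight vectors, Spearman ρ of
    the rankings (NaN when one vector is constant and ranks are undefined),
    and the overlap of the top-``k`` need sets.
    """
    from .concordance import ConstantProfileError, spearman_rho

    by_id = {gp.responder_id: gp for gp in recovered}
    out: list[RecoveryMetrics] = []
    for truth in truths:
        if truth.responder_id not in by_id:
            raise ValueError(f"no recovered weights for {truth.responder_id!r}")
        gp = by_id[truth.responder_id]
        tg = truth.global_weights
        if set(tg) != set(gp.global_weights):
            raise ValueError("need sets differ between truth and recovery")
        needs = list(tg)
        t = np.array([tg[n] for n in needs])
        r = np.array([gp.global_weights[n] for n in needs])
        l1 = float(np.abs(t - r).sum())
        try:
            rho = spearman_rho(t, r)
        except ConstantProfileError:
            rho = float("nan")
        top_t = set(sorted(needs, key=lambda n: -tg[n])[:k])
        top_r = set(sorted(needs, key=lambda n: -gp.global_weights[n])[:k])
        out.append(RecoveryMetrics(
            responder_id=truth.responder_id, l1_distance=l1,
            spearman_rho=rho, top_k_overlap=len(top_t & top_r), k=k,
        ))
    return out
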