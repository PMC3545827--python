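"""End-to-end study orchestration and reporting.

``run_study`` walks the whole chain for every responder: schedule the
questionnaires the hierarchy implies, ingest graded answers, build judgment
matrices, derive local/category weights by principal eigenvector, screen
consistency, aggregate global weights, and compute inter-responder
concordance at both the category and the need level.  Responders whose
worst consistency ratio exceeds the gate are flagged for re-elicitation and
excluded from concordance unless explicitly included.

``reproduce_case_tables`` replays the bundled CT-scanner case study from
its printed weights: the multiplicative aggregation identity on every
(responder, need) cell, and the published rank-correlation matrices at both
levels.  The case's consistency ratios are carried for display only — the
raw questionnaires behind them were never published, so they cannot be
recomputed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .concordance import ConcordanceResult, PriorityProfile, concordance_matrix, spearman_rho
from .elicitation import (
    DEFAULT_SCALE,
    JudgmentMatrix,
    JudgmentScale,
    ResponseError,
    build_judgment_matrix,
    build_schedule,
    ingest_responses,
)
from .fixtures import CaseStudy, load_ct_case
from .hierarchy import Advisory, Hierarchy, validate_advisories
from .priorities import (
    ConsistencyReport,
    GlobalPriorities,
    PriorityResult,
    consistency_report,
    global_weights,
    principal_priorities,
    rank_needs,
)

__all__ = [
    "StudyReport",
    "StudyError",
    "score_responder",
    "run_study",
    "reproduce_case_tables",
    "export_reports",
    "read_responses",
]


class StudyError(ValueError):
    """Study-level validation failure, carrying responder/node context."""


@dataclass(frozen=True)
class StudyReport:
    hierarchy: Hierarchy
    responder_ids: tuple[str, ...]
    priorities: dict[str, dict[str, PriorityResult]]    # responder → node → result
    consistency: dict[str, dict[str, ConsistencyReport]]
    global_priorities: dict[str, GlobalPriorities]
    advisories: list[Advisory]
    cr_threshold: float
    inconsistent_responders: tuple[str, ...]
    concordance_categories: ConcordanceResult | None
    concordance_needs: ConcordanceResult | None
    metadata: dict

    def flagged_actions(self) -> dict[str, str]:
        """Prescribed follow-up for responders failing the consistency gate."""
        return {
            rid: "consistency ratio above threshold: responder should answer "
                 "the questionnaire again"
            for rid in self.inconsistent_responders
        }


def read_responses(source: Union[str, Path, pd.DataFrame]) -> pd.DataFrame:
    """Load a responses table (responder_id, node_id, left_id, right_id, grade)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"responder_id", "node_id", "left_id", "right_id", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise StudyError(f"responses table missing columns: {sorted(missing)}")
    return df


def score_responder(
    hierarchy: Hierarchy,
    matrices: Mapping[str, JudgmentMatrix],
    responder_id: str = "",
    primary_threshold: float = 0.1,
    relaxed_threshold: float = 0.2,
) -> tuple[GlobalPriorities, dict[str, PriorityResult], dict[str, ConsistencyReport]]:
    """Weights and consistency for one responder's full matrix set."""
    prios: dict[str, PriorityResult] = {}
    cons: dict[str, ConsistencyReport] = {}
    for node_id, _ in hierarchy.comparison_nodes():
        if node_id not in matrices:
            raise StudyError(
                f"responder {responder_id!r}: no judgment matrix for node "
                f"{node_id!r}"
            )
        m = matrices[node_id]
        prios[node_id] = principal_priorities(m)
        cons[node_id] = consistency_report(m, primary_threshold, relaxed_threshold)
    gp = global_weights(
        prios[hierarchy.goal_id],
        [prios[c] for c in hierarchy.category_ids],
        responder_id=responder_id,
    )
    return gp, prios, cons


def run_study(
    hierarchy: Hierarchy,
    responses: Union[str, Path, pd.DataFrame, None] = None,
    matrices: Mapping[str, Mapping[str, JudgmentMatrix]] | None = None,
    scale: JudgmentScale = DEFAULT_SCALE,
    cr_threshold: float = 0.1,
    relaxed_threshold: float = 0.2,
    include_inconsistent: bool = False,
    alpha: float = 0.05,
    seed: int | None = None,
) -> StudyReport:
    """Score a whole study from a responses table or pre-built matrices.

    Concordance is computed over responders whose every node passes the
    consistency gate (``cr_threshold``); failing responders stay in the
    weight and consistency sections, flagged for re-elicitation, and join
    concordance only with ``include_inconsistent=True``.
    """
    if (responses is None) == (matrices is None):
        raise StudyError("provide exactly one of responses or matrices")

    per_responder: dict[str, dict[str, JudgmentMatrix]] = {}
    if responses is not None:
        df = read_responses(responses)
        schedules = {nid: build_schedule(nid, kids)
                     for nid, kids in hierarchy.comparison_nodes()}
        for rid, group in df.groupby("responder_id", sort=True):
            per_node: dict[str, JudgmentMatrix] = {}
            for node_id, sched in schedules.items():
                rows = group[group.node_id == node_id]
                try:
                    rs = ingest_responses(sched, rows.to_dict("records"),
                                          scale, responder_id=str(rid))
                    per_node[node_id] = build_judgment_matrix(
                        rs, sched.elements, scale
                    )
                except ResponseError as e:
                    raise StudyError(
                        f"responder {rid!r}, node {node_id!r}: {e}"
                    ) from e
            per_responder[str(rid)] = per_node
    else:
        per_responder = {rid: dict(m) for rid, m in matrices.items()}

    responder_ids = tuple(per_responder)
    priorities: dict[str, dict[str, PriorityResult]] = {}
    consistency: dict[str, dict[str, ConsistencyReport]] = {}
    gps: dict[str, GlobalPriorities] = {}
    for rid, mats in per_responder.items():
        gp, prios, cons = score_responder(
            hierarchy, mats, rid, cr_threshold, relaxed_threshold
        )
        priorities[rid] = prios
        consistency[rid] = cons
        gps[rid] = gp

    inconsistent = tuple(
        rid for rid in responder_ids
        if any(c.cr > cr_threshold for c in consistency[rid].values())
    )
    eligible = [rid for rid in responder_ids
                if include_inconsistent or rid not in inconsistent]

    conc_cat = conc_need = None
    if len(eligible) >= 2:
        cat_profiles = [
            PriorityProfile(
                responder_id=rid,
                item_ids=hierarchy.category_ids,
                weights=np.array([gps[rid].category_weights[c]
                                  for c in hierarchy.category_ids]),
            )
            for rid in eligible
        ]
        need_profiles = [
            PriorityProfile(
                responder_id=rid,
                item_ids=hierarchy.need_ids,
                weights=np.array([gps[rid].global_weights[n]
                                  for n in hierarchy.need_ids]),
            )
            for rid in eligible
        ]
        conc_cat = concordance_matrix(cat_profiles, alpha)
        conc_need = concordance_matrix(need_profiles, alpha)

    from .hierarchy import dump_hierarchy

    config_hash = hashlib.sha256(
        (dump_hierarchy(hierarchy) + scale.name + f"{cr_threshold}|{alpha}").encode()
    ).hexdigest()[:16]
    metadata = {
        "config_hash": config_hash,
        "seed": seed,
        "n_responders": len(responder_ids),
        "cr_threshold": cr_threshold,
        "alpha": alpha,
        "generated_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return StudyReport(
        hierarchy=hierarchy,
        responder_ids=responder_ids,
        priorities=priorities,
        consistency=consistency,
        global_priorities=gps,
        advisories=validate_advisories(hierarchy),
        cr_threshold=cr_threshold,
        inconsistent_responders=inconsistent,
        concordance_categories=conc_cat,
        concordance_needs=conc_need,
        metadata=metadata,
    )


# --------------------------------------------------------------------------
# case-study reproduction


@dataclass(frozen=True)
class CaseReproduction:
    """Outcome of replaying the bundled case study from its printed weights."""

    aggregation_max_abs_error: float     # max |GW − LW×CW| over all cells
    aggregation_ok: bool
    need_rho: pd.DataFrame               # recomputed, responder × responder
    need_rho_max_dev: float              # vs published printed values
    need_rho_ok: bool
    category_rho: pd.DataFrame
    category_ones_ok: bool               # published ρ=1 pairs recovered exactly
    top5: dict[str, list[str]]           # per responder, from printed GW
    checks_passed: bool


def reproduce_case_tables(case: CaseStudy | None = None) -> CaseReproduction:
    """Replay the CT-scanner case from its printed two-decimal weights.

    Three checks: (a) GW = LW × CW holds within ±0.01 on all 60 cells
    (two-decimal rounding slack); (b) the need-level Spearman matrix
    recomputed from printed global weights matches every published entry
    within ±0.005; (c) every published category-level ρ = 1 pair is
    recovered exactly.
    """
    case = case or load_ct_case()
    h = case.hierarchy

    # (a) multiplicative aggregation identity, cell by cell
    errs = []
    for _, row in case.need_weights.iterrows():
        cw = float(
            case.category_weights.set_index("category_id")
            .at[row.category_id, row.responder_id]
        )
        errs.append(abs(row.GW - row.LW * cw))
    agg_max = float(max(errs))
    agg_ok = agg_max <= 0.01

    # (b, c) concordance from printed columns
    responders = case.responders
    need_rho = pd.DataFrame(np.eye(len(responders)), index=responders,
                            columns=responders)
    cat_rho = need_rho.copy()
    for i, a in enumerate(responders):
        for j, b in enumerate(responders):
            if j <= i:
                continue
            ga = list(case.gw_profile(a).values())
            gb = list(case.gw_profile(b).values())
            need_rho.iloc[i, j] = need_rho.iloc[j, i] = spearman_rho(ga, gb)
            ca = list(case.cw_profile(a).values())
            cb = list(case.cw_profile(b).values())
            cat_rho.iloc[i, j] = cat_rho.iloc[j, i] = spearman_rho(ca, cb)

    need_devs = []
    for key, entry in case.published_rho["needs"].items():
        if entry is None:
            continue
        a, b = key.split("|")
        need_devs.append(abs(need_rho.at[a, b] - entry["rho"]))
    need_max = float(max(need_devs))
    need_ok = need_max <= 0.005

    ones_ok = all(
        cat_rho.at[key.split("|")[0], key.split("|")[1]] == 1.0
        for key, entry in case.published_rho["categories"].items()
        if entry is not None and entry["rho"] == 1.0
    )

    top5 = {}
    for rid in responders:
        gp = GlobalPriorities(
            responder_id=rid,
            category_weights=case.cw_profile(rid),
            local_weights=case.lw_profile(rid),
            global_weights=case.gw_profile(rid),
            category_of={n: h.category_of(n) for n in h.need_ids},
        )
        top5[rid] = [r.need_id for r in rank_needs(gp, k=5)]

    return CaseReproduction(
        aggregation_max_abs_error=agg_max,
        aggregation_ok=agg_ok,
        need_rho=need_rho,
        need_rho_max_dev=need_max,
        need_rho_ok=need_ok,
        category_rho=cat_rho,
        category_ones_ok=ones_ok,
        top5=top5,
        checks_passed=agg_ok and need_ok and ones_ok,
    )


# --------------------------------------------------------------------------
# export


def _concordance_frames(conc: ConcordanceResult) -> dict[str, pd.DataFrame]:
    ids = list(conc.responder_ids)
    return {
        "rho": pd.DataFrame(conc.rho, index=ids, columns=ids),
        "pvalues": pd.DataFrame(conc.pvalues, index=ids, columns=ids),
        "significant": pd.DataFrame(conc.significant, index=ids, columns=ids),
    }


def export_reports(report: StudyReport, out_dir: Union[str, Path]) -> dict:
    """Write weights, consistency and concordance CSVs plus a JSON manifest.

    Output is deterministic for a given report: re-exporting the same
    report yields byte-identical files.  The manifest lists every file with
    its sha256 checksum; concordance files are omitted (and noted) when
    fewer than two responders were eligible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = report.hierarchy
    written: dict[str, Path] = {}

    rows = []
    for rid in report.responder_ids:
        gp = report.global_priorities[rid]
        for need in h.need_ids:
            cat = gp.category_of[need]
            rows.append({
                "responder_id": rid, "category_id": cat, "need_id": need,
                "LW": gp.local_weights[need],
                "CW": gp.category_weights[cat],
                "GW": gp.global_weights[need],
            })
    weights = pd.DataFrame(rows)
    weights.to_csv(out / "weights.csv", index=False, float_format="%.12g")
    written["weights"] = out / "weights.csv"

    # rounded presentation table: GW with parenthesized LW, per responder
    pres = pd.DataFrame({"need_id": list(h.need_ids)})
    for rid in report.responder_ids:
        gp = report.global_priorities[rid]
        pres[rid] = [
            f"{gp.global_weights[n]:.2f} ({gp.local_weights[n]:.2f})"
            for n in h.need_ids
        ]
    pres.to_csv(out / "weights_table.csv", index=False)
    written["weights_table"] = out / "weights_table.csv"

    cons = pd.DataFrame({
        "node_id": [nid for nid, _ in h.comparison_nodes()],
    })
    for rid in report.responder_ids:
        cons[rid] = [report.consistency[rid][nid].cr
                     for nid, _ in h.comparison_nodes()]
    cons.to_csv(out / "consistency.csv", index=False, float_format="%.12g")
    written["consistency"] = out / "consistency.csv"

    notes = []
    for level, conc in (("categories", report.concordance_categories),
                        ("needs", report.concordance_needs)):
        if conc is None:
            notes.append(f"concordance_{level} omitted: fewer than 2 eligible "
                         "responders")
            continue
        for name, frame in _concordance_frames(conc).items():
            path = out / f"concordance_{level}_{name}.csv"
            frame.to_csv(path, float_format="%.12g")
            written[f"concordance_{level}_{name}"] = path

    manifest = {
        "metadata": report.metadata,
        "advisories": [a.message for a in report.advisories],
        "inconsistent_responders": list(report.inconsistent_responders),
        "notes": notes,
        "files": {
            key: {
                "path": p.name,
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            }
            for key, p in written.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
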