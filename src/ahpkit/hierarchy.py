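"""Goal → category → need trees.

The hierarchy is the backbone of an AHP needs-elicitation study: one goal
node, an ordered set of categories beneath it, and the elicited needs as
leaves under their categories.  Every pairwise-comparison questionnaire
corresponds to one internal node (the goal, comparing categories, or a
category, comparing its needs), so the tree determines exactly which
judgment matrices exist and in what element order.

Depth is fixed at three levels.  Global weights are computed as the product
of a need's local weight and its category's weight, an aggregation that is
only well defined for a two-level decomposition; deeper trees are rejected
rather than silently mis-aggregated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import yaml

__all__ = [
    "NeedNode",
    "Hierarchy",
    "HierarchyError",
    "Advisory",
    "load_hierarchy",
    "dump_hierarchy",
    "validate_advisories",
]

#: More children than this in one node draws an advisory: pairwise burden
#: grows as n(n-1)/2 and inconsistency rises sharply past four elements.
MAX_RECOMMENDED_CHILDREN = 4


class HierarchyError(ValueError):
    """Structural problem in a hierarchy document."""


@dataclass(frozen=True)
class NeedNode:
    """One node of the tree: the goal, a category, or a leaf need."""

    id: str
    label: str
    kind: str  # "goal" | "category" | "need"
    children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("goal", "category", "need"):
            raise HierarchyError(f"unknown node kind {self.kind!r} for {self.id!r}")
        if self.kind == "need" and self.children:
            raise HierarchyError(
                f"need {self.id!r} has children; the tree is fixed at "
                "goal/category/need depth"
            )


@dataclass(frozen=True)
class Hierarchy:
    """A validated three-level tree of needs.

    ``category_ids`` and ``need_ids`` preserve document order, which is
    authoritative for questionnaire schedules and every downstream report.
    """

    nodes: dict[str, NeedNode]
    goal_id: str
    category_ids: tuple[str, ...]
    need_ids: tuple[str, ...]

    @property
    def goal(self) -> NeedNode:
        return self.nodes[self.goal_id]

    def children_of(self, node_id: str) -> tuple[str, ...]:
        return self.nodes[node_id].children

    def category_of(self, need_id: str) -> str:
        """Parent category of a leaf need."""
        for cat in self.category_ids:
            if need_id in self.nodes[cat].children:
                return cat
        raise KeyError(f"{need_id!r} is not a need of this hierarchy")

    def comparison_nodes(self) -> list[tuple[str, tuple[str, ...]]]:
        """Every node that generates a questionnaire, with its element order.

        The goal node (comparing categories) comes first, then each category
        (comparing its needs) in document order.
        """
        out = [(self.goal_id, self.category_ids)]
        for cat in self.category_ids:
            out.append((cat, self.nodes[cat].children))
        return out

    def label_of(self, node_id: str) -> str:
        return self.nodes[node_id].label


@dataclass(frozen=True)
class Advisory:
    """Non-fatal design recommendation breach."""

    node_id: str
    n_children: int
    message: str


def _build(doc: dict) -> Hierarchy:
    if not isinstance(doc, dict) or "goal" not in doc:
        raise HierarchyError("document must declare a 'goal' mapping")
    goal = doc["goal"]
    goal_id = str(goal.get("id", "goal"))
    goal_label = str(goal.get("label", goal_id))
    categories = doc.get("categories")
    if not categories:
        raise HierarchyError("document declares no categories")

    nodes: dict[str, NeedNode] = {}
    cat_ids: list[str] = []
    need_ids: list[str] = []

    def add(node: NeedNode) -> None:
        if node.id in nodes:
            raise HierarchyError(f"duplicate node id {node.id!r}")
        nodes[node.id] = node

    for cat in categories:
        cid = str(cat["id"])
        children = cat.get("children") or []
        if len(children) < 2:
            raise HierarchyError(
                f"category {cid!r} has {len(children)} children; at least 2 "
                "are required to form a pairwise comparison"
            )
        child_ids = []
        for ch in children:
            nid = str(ch["id"])
            if ch.get("children"):
                raise HierarchyError(
                    f"need {nid!r} has children; hierarchies deeper than "
                    "goal/category/need are not supported"
                )
            add(NeedNode(id=nid, label=str(ch.get("label", nid)), kind="need"))
            child_ids.append(nid)
            need_ids.append(nid)
        add(NeedNode(id=cid, label=str(cat.get("label", cid)), kind="category",
                     children=tuple(child_ids)))
        cat_ids.append(cid)

    add(NeedNode(id=goal_id, label=goal_label, kind="goal", children=tuple(cat_ids)))

    # needs attached directly to the goal arrive as 1-child "categories" or
    # as goal children without their own children list
    for extra in goal.get("children", []) or []:
        raise HierarchyError(
            "needs must be attached to a category, not directly to the goal"
        )

    h = Hierarchy(nodes=nodes, goal_id=goal_id,
                  category_ids=tuple(cat_ids), need_ids=tuple(need_ids))
    assert len(h.need_ids) == sum(len(h.nodes[c].children) for c in h.category_ids)
    return h


def load_hierarchy(source: Union[str, Path, dict]) -> Hierarchy:
    """Load and validate a hierarchy from YAML/JSON text, a path, or a dict.

    The document declares a goal, an ordered list of categories, and each
    category's ordered children.  Document order is preserved everywhere.
    """
    if isinstance(source, dict):
        return _build(source)
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise HierarchyError("hierarchy document is not a mapping")
    return _build(doc)


def dump_hierarchy(h: Hierarchy, path: Union[str, Path, None] = None) -> str:
    """Serialize to canonical YAML; ``load_hierarchy`` round-trips exactly."""
    doc = {
        "goal": {"id": h.goal_id, "label": h.goal.label},
        "categories": [
            {
                "id": cid,
                "label": h.nodes[cid].label,
                "children": [
                    {"id": nid, "label": h.nodes[nid].label}
                    for nid in h.nodes[cid].children
                ],
            }
            for cid in h.category_ids
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def validate_advisories(h: Hierarchy) -> list[Advisory]:
    """Flag nodes holding more than four elements.

    Keeping at most four elements per node (three is better still) limits
    questionnaire length and the responder inconsistency that grows with it.
    Breaches are advisories, never errors.
    """
    out: list[Advisory] = []
    for node_id, children in h.comparison_nodes():
        if len(children) > MAX_RECOMMENDED_CHILDREN:
            out.append(
                Advisory(
                    node_id=node_id,
                    n_children=len(children),
                    message=(
                        f"node {node_id!r} compares {len(children)} elements; "
                        f"no more than {MAX_RECOMMENDED_CHILDREN} are recommended "
                        "— consider an extra hierarchy level"
                    ),
                )
            )
    return out
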