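"""Pairwise-comparison design: verbal scales, schedules, judgment matrices.

Responders never see numbers.  They answer verbal questions ("how important
do you consider X compared to Y?") on a graded vocabulary; each grade maps
to a ratio on a reciprocal-symmetric grid.  The default grid is the adapted
five-anchor scale {1/5 … 5}: lay responders rarely use more than the three
positive anchors (equally / more / much more important), and a compact scale
measurably reduces inconsistency.  The classic 1–9 grid is available for
studies that want it.

A comparison schedule lists each unordered pair of a node's elements exactly
once, oriented so every element appears on the left and the right of the
question as evenly as possible (a known presentation bias pushes responders
to favour the left element).  For three elements the schedule is the cycle
A–B, B–C, C–A, whose third question is the redundant transitivity probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JudgmentScale",
    "ADAPTED_FIVE_SCALE",
    "SAATY_NINE_SCALE",
    "DEFAULT_SCALE",
    "ComparisonSchedule",
    "ResponseSet",
    "JudgmentMatrix",
    "ResponseError",
    "build_schedule",
    "ingest_responses",
    "build_judgment_matrix",
    "render_questionnaire",
]


class ResponseError(ValueError):
    """Malformed, incomplete or contradictory response data."""


@dataclass(frozen=True)
class JudgmentScale:
    """Ordered verbal grades and their numeric ratios.

    Grades run from the strongest "less important" to the strongest "more
    important"; the middle grade is exact equality (ratio 1) and mirrored
    grades carry exact reciprocal ratios.  Ratios are stored as
    :class:`~fractions.Fraction` so reciprocity is exact, not a float
    artifact.
    """

    name: str
    grades: tuple[str, ...]
    values: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        n = len(self.grades)
        if n != len(self.values) or n % 2 == 0:
            raise ValueError("scale needs an odd number of grade/value pairs")
        mid = n // 2
        if self.values[mid] != 1:
            raise ValueError("middle grade must map to 1 (equal importance)")
        for i in range(n):
            if self.values[i] * self.values[n - 1 - i] != 1:
                raise ValueError("grades must be reciprocal-symmetric")
        if any(v <= 0 for v in self.values):
            raise ValueError("scale ratios must be positive")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return self.grades

    def _index(self, grade: str) -> int:
        low = grade.strip().lower()
        for i, g in enumerate(self.grades):
            if g.lower() == low:
                return i
        raise ResponseError(f"unknown grade {grade!r}; expected one of {self.grades}")

    def value(self, grade: str) -> Fraction:
        """Numeric ratio of a verbal grade (case-insensitive)."""
        return self.values[self._index(grade)]

    def mirror(self, grade: str) -> str:
        """The grade a responder would give with the question flipped."""
        return self.grades[len(self.grades) - 1 - self._index(grade)]

    def nearest_grade(self, ratio: float) -> str:
        """Grade whose ratio is nearest in log space (reciprocal-consistent)."""
        if ratio <= 0:
            raise ValueError("ratio must be positive")
        logs = np.log([float(v) for v in self.values])
        return self.grades[int(np.argmin(np.abs(logs - math.log(ratio))))]

    def snap(self, ratio: float) -> float:
        """Nearest grid ratio in log space."""
        return float(self.value(self.nearest_grade(ratio)))


def grade_to_value(grade: str, scale: "JudgmentScale") -> Fraction:
    """Numeric ratio for a verbal grade on the given scale."""
    return scale.value(grade)


ADAPTED_FIVE_SCALE = JudgmentScale(
    name="adapted-five",
    grades=(
        "much less important",
        "moderately less important",
        "less important",
        "slightly less important",
        "equally important",
        "slightly more important",
        "more important",
        "moderately more important",
        "much more important",
    ),
    values=(
        Fraction(1, 5), Fraction(1, 4), Fraction(1, 3), Fraction(1, 2),
        Fraction(1), Fraction(2), Fraction(3), Fraction(4), Fraction(5),
    ),
)
"""Adapted five-anchor scale with in-between grades; ratios {1/5 … 5}."""

SAATY_NINE_SCALE = JudgmentScale(
    name="saaty-nine",
    grades=tuple(f"1/{k}" for k in range(9, 1, -1)) + ("1",) + tuple(str(k) for k in range(2, 10)),
    values=tuple(Fraction(1, k) for k in range(9, 1, -1)) + (Fraction(1),) + tuple(Fraction(k) for k in range(2, 10)),
)
"""Classic fundamental scale, grades named by their ratios 1/9 … 9."""

DEFAULT_SCALE = ADAPTED_FIVE_SCALE


@dataclass(frozen=True)
class ComparisonSchedule:
    """Ordered left/right question pairs for one node."""

    node_id: str
    pairs: tuple[tuple[str, str], ...]

    @property
    def elements(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for l, r in self.pairs:
            seen.setdefault(l)
            seen.setdefault(r)
        return tuple(seen)

    def side_counts(self) -> dict[str, tuple[int, int]]:
        """(left, right) appearance count per element."""
        counts: dict[str, list[int]] = {}
        for l, r in self.pairs:
            counts.setdefault(l, [0, 0])[0] += 1
            counts.setdefault(r, [0, 0])[1] += 1
        return {k: (v[0], v[1]) for k, v in counts.items()}


def build_schedule(node_id: str, children: Sequence[str]) -> ComparisonSchedule:
    """Deterministic balanced schedule over all n(n-1)/2 pairs.

    Uses the cyclic-distance construction: for each offset d = 1 … ⌊n/2⌋ the
    pairs (i, i+d mod n) are emitted in element order.  For d < n/2 every
    element appears exactly once on each side per offset; for even n the
    half-offset round adds one appearance per element, so left/right counts
    differ by at most one — exact balance is impossible when each element
    appears an odd number of times.  For n = 3 this is the cycle
    (A,B), (B,C), (C,A) whose closing question probes transitivity.
    """
    ids = list(children)
    n = len(ids)
    if n < 2:
        raise ValueError(f"node {node_id!r} has {n} children; need at least 2")
    if len(set(ids)) != n:
        raise ValueError(f"node {node_id!r} has duplicate children")
    pairs: list[tuple[str, str]] = []
    for d in range(1, n // 2 + 1):
        limit = n if (2 * d != n) else n // 2
        for i in range(limit):
            pairs.append((ids[i], ids[(i + d) % n]))
    assert len(pairs) == n * (n - 1) // 2
    return ComparisonSchedule(node_id=node_id, pairs=tuple(pairs))


@dataclass(frozen=True)
class ResponseSet:
    """One responder's complete graded answers for one node's schedule."""

    responder_id: str
    node_id: str
    grades: Mapping[tuple[str, str], str]  # (left, right) in schedule orientation


def ingest_responses(
    schedule: ComparisonSchedule,
    rows: Iterable[Mapping[str, str]],
    scale: JudgmentScale = DEFAULT_SCALE,
    responder_id: str | None = None,
) -> ResponseSet:
    """Collect raw answer rows into a complete :class:`ResponseSet`.

    Rows carry ``left_id``, ``right_id`` and ``grade`` (plus optionally
    ``responder_id``/``node_id``).  A row answered in the flipped
    orientation is stored under the scheduled orientation with its mirror
    grade.  Missing pairs, contradictory duplicates and unknown grades are
    errors — a responder with contradictions re-answers the questionnaire
    rather than having answers averaged.
    """
    scheduled = set(schedule.pairs)
    grades: dict[tuple[str, str], str] = {}
    rid = responder_id
    for row in rows:
        if rid is None and "responder_id" in row:
            rid = str(row["responder_id"])
        left, right = str(row["left_id"]), str(row["right_id"])
        grade = str(row["grade"])
        scale._index(grade)  # validates vocabulary, raises ResponseError
        if (left, right) in scheduled:
            key, stored = (left, right), grade
        elif (right, left) in scheduled:
            key, stored = (right, left), scale.mirror(grade)
        else:
            raise ResponseError(
                f"pair ({left}, {right}) is not scheduled for node "
                f"{schedule.node_id!r}"
            )
        canonical = scale.grades[scale._index(stored)]
        if key in grades and grades[key] != canonical:
            raise ResponseError(
                f"contradictory duplicate answer for pair {key} of node "
                f"{schedule.node_id!r}: {grades[key]!r} vs {canonical!r}"
            )
        grades[key] = canonical
    missing = [p for p in schedule.pairs if p not in grades]
    if missing:
        raise ResponseError(
            f"incomplete responses for node {schedule.node_id!r}; "
            f"missing pairs: {missing}"
        )
    return ResponseSet(responder_id=rid or "", node_id=schedule.node_id,
                       grades=dict(grades))


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix for one node.

    Entry ``a[i, j]`` is the judged importance ratio of element i over
    element j: values above 1 mean the row element dominates.  The diagonal
    is 1 and the lower triangle holds exact float reciprocals of the upper,
    so ``a * a.T`` is the all-ones matrix by construction.
    """

    node_id: str
    elements: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        n = len(self.elements)
        if a.shape != (n, n):
            raise ValueError("matrix shape does not match element count")
        if not np.all(a > 0):
            raise ValueError("judgment matrix entries must be strictly positive")
        if not np.allclose(np.diag(a), 1.0, rtol=0, atol=0):
            raise ValueError("judgment matrix diagonal must be exactly 1")
        if not np.allclose(a * a.T, 1.0, rtol=1e-9, atol=1e-12):
            raise ValueError("judgment matrix must be reciprocal")

    @property
    def n(self) -> int:
        return len(self.elements)

    @classmethod
    def from_ratios(cls, node_id: str, elements: Sequence[str],
                    upper: Mapping[tuple[str, str], float]) -> "JudgmentMatrix":
        """Build from upper-triangle ratios; reciprocals filled exactly."""
        els = tuple(elements)
        idx = {e: i for i, e in enumerate(els)}
        a = np.eye(len(els))
        for (l, r), v in upper.items():
            i, j = idx[l], idx[r]
            v = float(v)
            a[i, j] = v
            a[j, i] = 1.0 / v
        return cls(node_id=node_id, elements=els, values=a)


def build_judgment_matrix(
    responses: ResponseSet,
    elements: Sequence[str],
    scale: JudgmentScale = DEFAULT_SCALE,
) -> JudgmentMatrix:
    """Convert graded answers to the node's reciprocal judgment matrix.

    ``a[i, j]`` is the scale ratio of the grade given with i on the left and
    j on the right; the mirrored entry is forced to the exact reciprocal.
    """
    els = tuple(elements)
    known = set(els)
    upper: dict[tuple[str, str], float] = {}
    for (l, r), grade in responses.grades.items():
        if l not in known or r not in known:
            raise ResponseError(
                f"response pair ({l}, {r}) references unknown elements for "
                f"node {responses.node_id!r}"
            )
        upper[(l, r)] = float(scale.value(grade))
    need = {(els[i], els[j]) for i in range(len(els)) for j in range(i + 1, len(els))}
    have = {tuple(sorted(p)) for p in upper}
    if {tuple(sorted(p)) for p in need} != have:
        raise ResponseError(
            f"incomplete responses for node {responses.node_id!r}"
        )
    return JudgmentMatrix.from_ratios(responses.node_id, els, upper)


QUESTION_STEM = (
    "In the selection of a new CT scanner, according to your experience, "
    "how important do you consider {left} compared to {right}?"
)


def render_questionnaire(
    schedule: ComparisonSchedule,
    labels: Mapping[str, str] | None = None,
    scale: JudgmentScale = DEFAULT_SCALE,
    stem: str = QUESTION_STEM,
) -> str:
    """Plain-text questionnaire for one node's schedule."""
    labels = labels or {}
    lines = [f"Questionnaire for node: {schedule.node_id}",
             f"Answer each question with one of: {', '.join(scale.vocabulary)}",
             ""]
    for k, (l, r) in enumerate(schedule.pairs, 1):
        lines.append(f"{k}. " + stem.format(left=labels.get(l, l),
                                            right=labels.get(r, r)))
    return "\n".join(lines) + "\n"
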