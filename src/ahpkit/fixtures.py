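"""Bundled CT-scanner case study.

A published needs-elicitation exercise for a multi-slice CT scanner in a
medium-size public hospital: five senior clinicians (radiology, ear
surgery, elective neurology, emergency neurology, emergency medicine)
prioritized 12 needs in 4 categories.  The bundle carries the printed
two-decimal results — category weights, local/global need weights,
per-questionnaire consistency ratios, and the published rank-correlation
entries — which serve as regression fixtures: the raw questionnaires were
never published, so the weights are inputs here, not something this
package recomputes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy, load_hierarchy

__all__ = ["CaseStudy", "load_ct_case", "FixtureIntegrityError", "RESPONDERS"]

RESPONDERS = (
    "radiology", "ear_surgery", "neurology", "emergency_neurology", "emergency",
)

_CHECKSUMS = {
    "ct_hierarchy.yaml": "967fd81182fe61aedb9c78f59f90a7c5a07266dd17cc20b59188b814055a495b",
    "ct_category_weights.csv": "213d145a1221e82c1ba9d461555a3d6dd5c4a7571d4c6419d9f82e6046e065d9",
    "ct_need_weights.csv": "10703c9f499d159eb0fa2578a98dc9d462702727dc9e5e93876fa1b6f6ff40e0",
    "ct_consistency.csv": "4351c8e192b6064dc166ba79da93b30369dad6a0f662afdb53c5c604c29d8635",
    "ct_concordance.json": "a3942b453ae7aee0232c86d431318607530954cb8ab50f3e3658f4b2dcd75e12",
}


class FixtureIntegrityError(RuntimeError):
    """Bundled case-study data does not match its recorded checksum."""


def _read(name: str) -> bytes:
    data = (resources.files("ahpkit") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"{name}: checksum {digest} != expected {_CHECKSUMS[name]}"
        )
    return data


@dataclass(frozen=True)
class CaseStudy:
    """The CT-scanner study's printed results, as tidy frames.

    ``category_weights`` and ``consistency`` are node × responder tables;
    ``need_weights`` is long-form with printed LW and GW per (responder,
    need); ``published_rho`` holds the published pairwise Spearman entries
    (``None`` where the source suppressed a non-significant pair).
    """

    hierarchy: Hierarchy
    category_weights: pd.DataFrame
    need_weights: pd.DataFrame
    consistency: pd.DataFrame
    published_rho: dict

    @property
    def responders(self) -> tuple[str, ...]:
        return RESPONDERS

    def gw_profile(self, responder: str) -> dict[str, float]:
        """Printed global weights for one responder, in hierarchy order."""
        sub = self.need_weights[self.need_weights.responder_id == responder]
        gw = dict(zip(sub.need_id, sub.GW))
        return {n: gw[n] for n in self.hierarchy.need_ids}

    def lw_profile(self, responder: str) -> dict[str, float]:
        sub = self.need_weights[self.need_weights.responder_id == responder]
        lw = dict(zip(sub.need_id, sub.LW))
        return {n: lw[n] for n in self.hierarchy.need_ids}

    def cw_profile(self, responder: str) -> dict[str, float]:
        col = self.category_weights.set_index("category_id")[responder]
        return {c: float(col[c]) for c in self.hierarchy.category_ids}


def load_ct_case() -> CaseStudy:
    """Load and integrity-check the bundled CT-scanner case study."""
    import io

    hierarchy = load_hierarchy(_read("ct_hierarchy.yaml").decode())
    cat = pd.read_csv(io.BytesIO(_read("ct_category_weights.csv")))
    needs = pd.read_csv(io.BytesIO(_read("ct_need_weights.csv")))
    cons = pd.read_csv(io.BytesIO(_read("ct_consistency.csv")))
    rho = json.loads(_read("ct_concordance.json").decode())
    return CaseStudy(
        hierarchy=hierarchy,
        category_weights=cat,
        need_weights=needs,
        consistency=cons,
        published_rho=rho,
    )
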