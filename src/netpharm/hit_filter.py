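"""Virtual-screening hit selection and target eligibility.

A (molecule, target) pair is a *hit* when the molecule's docking score
against the target beats both the target's original co-crystal ligand and
an absolute cutoff (6.0 by convention here; higher score = stronger
predicted binding).  Targets then pass three eligibility criteria before
they enter the drug-target network: human origin, at least one pathway
annotation, and at least one of those pathways carrying a disease
annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .annotations import AnnotationMap

__all__ = [
    "DockingRecord",
    "TargetMeta",
    "select_hits",
    "eligible_targets",
    "restrict_hits",
]

DEFAULT_SCORE_THRESHOLD = 6.0


@dataclass(frozen=True)
class DockingRecord:
    """One docking observation: a molecule scored against a target
    structure, alongside that structure's reference-ligand score."""

    molecule_id: str
    target_id: str
    score: float
    reference_score: float

    def __post_init__(self):
        if not self.molecule_id or not self.target_id:
            raise ValueError("molecule_id and target_id must be nonempty")
        if not math.isfinite(self.score):
            raise ValueError("non-finite docking score for %s/%s"
                             % (self.molecule_id, self.target_id))
        if not math.isfinite(self.reference_score):
            raise ValueError("non-finite reference score for %s/%s"
                             % (self.molecule_id, self.target_id))


@dataclass(frozen=True)
class TargetMeta:
    """Target annotation: source organism and pathway memberships.
    An empty pathway set is allowed — such targets fail eligibility."""

    target_id: str
    organism: str
    pathway_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.target_id:
            raise ValueError("target_id must be nonempty")
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))


def select_hits(
    records: Iterable[DockingRecord],
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> set[tuple[str, str]]:
    """Hit pairs: best score per (molecule, target) strictly above both the
    target's minimum reference-ligand score and *threshold*.

    Both comparisons are strict, so ties at either bound are excluded.
    Multiple records for one pair (several crystal structures) collapse to
    the most permissive composition: the pair's best score is compared
    against the smallest reference score seen for that target.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    best: dict[tuple[str, str], float] = {}
    ref_min: dict[str, float] = {}
    for rec in records:
        pair = (rec.molecule_id, rec.target_id)
        if pair not in best or rec.score > best[pair]:
            best[pair] = rec.score
        t = rec.target_id
        if t not in ref_min or rec.reference_score < ref_min[t]:
            ref_min[t] = rec.reference_score
    return {
        pair
        for pair, s in best.items()
        if s > ref_min[pair[1]] and s > threshold
    }


def eligible_targets(
    targets: Iterable[TargetMeta],
    pathway_disease: AnnotationMap,
    organism: str = "human",
) -> set[str]:
    """Targets passing the three eligibility criteria.

    Kept iff (a) the source organism matches *organism* case-insensitively,
    (b) the target has at least one pathway annotation, and (c) at least
    one of those pathways carries a disease annotation in *pathway_disease*.
    Unknown pathway ids simply contribute no disease.
    """
    wanted = organism.strip().lower()
    kept: set[str] = set()
    for t in targets:
        if t.organism.strip().lower() != wanted:
            continue
        if not t.pathway_ids:
            continue
        if any(pathway_disease.get(pw) for pw in t.pathway_ids):
            kept.add(t.target_id)
    return kept


def restrict_hits(
    hits: Iterable[tuple[str, str]], kept_targets: set[str]
) -> set[tuple[str, str]]:
    """Hits whose target survived eligibility; molecules left with no hit
    simply disappear from the downstream network."""
    return {(m, t) for m, t in hits if t in kept_targets}
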