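"""Clinical phenotype layers: disease categories, symptom frequencies and
the Cold/Hot ZHENG partition.

ZHENG is the traditional-Chinese-medicine syndrome classification; here a
disease carries a nonempty label subset of {Cold, Hot}.  Counting is
inclusive: the reported Cold and Hot totals each include the dual-labeled
diseases, so distinct = |Cold| + |Hot| - |both|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotations import AnnotationMap

__all__ = [
    "ZhengLabelSet",
    "ZhengPartition",
    "category_proportions",
    "symptom_counts",
    "classify_zheng",
]

ZHENG_LABELS = frozenset({"Cold", "Hot"})


@dataclass(frozen=True)
class ZhengLabelSet:
    """ZHENG labels for one disease: a nonempty subset of {Cold, Hot}."""

    disease_id: str
    labels: frozenset[str]

    def __post_init__(self):
        if not self.disease_id:
            raise ValueError("disease_id must be nonempty")
        labels = frozenset(self.labels)
        if not labels:
            raise ValueError("disease %r has an empty ZHENG label set" % self.disease_id)
        if not labels <= ZHENG_LABELS:
            raise ValueError(
                "disease %r has labels outside {Cold, Hot}: %s"
                % (self.disease_id, sorted(labels - ZHENG_LABELS))
            )
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class ZhengPartition:
    """Disjoint ZHENG partition with inclusive summary counts."""

    cold_only: frozenset[str]
    hot_only: frozenset[str]
    both: frozenset[str]

    @property
    def n_cold(self) -> int:
        """Cold count, inclusive of dual-labeled diseases."""
        return len(self.cold_only) + len(self.both)

    @property
    def n_hot(self) -> int:
        return len(self.hot_only) + len(self.both)

    @property
    def n_both(self) -> int:
        return len(self.both)

    @property
    def n_total(self) -> int:
        return len(self.cold_only) + len(self.hot_only) + len(self.both)


def category_proportions(
    disease_categories: AnnotationMap, diseases: Iterable[str]
) -> pd.DataFrame:
    """Category composition of a disease set.

    Each (disease, category) assignment counts once; a disease filed under
    several categories contributes one assignment per category.  Percentage
    is the share of all assignments, to two decimals.  Columns: category,
    count, percentage; rows sorted by count descending, then category.
    """
    counts: dict[str, int] = {}
    for d in set(diseases):
        for c in disease_categories.get(d):
            counts[c] = counts.get(c, 0) + 1
    total = sum(counts.values())
    rows = [
        {"category": c, "count": n, "percentage": round(100.0 * n / total, 2)}
        for c, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["category", "count", "percentage"])
    if len(df):
        df = df.sort_values(
            ["count", "category"], ascending=[False, True], ignore_index=True
        )
    return df


def symptom_counts(
    disease_symptoms: AnnotationMap, diseases: Iterable[str]
) -> pd.DataFrame:
    """Number of distinct diseases in the set presenting each symptom.

    The annotation map already de-duplicates symptoms within one disease,
    so a repeated listing counts once.  Columns: symptom, n_diseases;
    sorted by count descending, then symptom.
    """
    wanted = set(diseases)
    counts: dict[str, int] = {}
    for d in wanted:
        for s in disease_symptoms.get(d):
            counts[s] = counts.get(s, 0) + 1
    df = pd.DataFrame(
        [{"symptom": s, "n_diseases": n} for s, n in counts.items()],
        columns=["symptom", "n_diseases"],
    )
    if len(df):
        df = df.sort_values(
            ["n_diseases", "symptom"], ascending=[False, True], ignore_index=True
        )
    return df


def classify_zheng(labels: Iterable[ZhengLabelSet]) -> ZhengPartition:
    """Partition labeled diseases into cold-only / hot-only / dual-labeled.

    Multiple records for one disease merge by label union.  The three sets
    are pairwise disjoint and cover every labeled disease.
    """
    merged: dict[str, set[str]] = {}
    for rec in labels:
        merged.setdefault(rec.disease_id, set()).update(rec.labels)
    cold_only = frozenset(d for d, ls in merged.items() if ls == {"Cold"})
    hot_only = frozenset(d for d, ls in merged.items() if ls == {"Hot"})
    both = frozenset(d for d, ls in merged.items() if ls == {"Cold", "Hot"})
    return ZhengPartition(cold_only=cold_only, hot_only=hot_only, both=both)
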