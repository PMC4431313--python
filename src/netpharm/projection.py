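"""Cross-scale network composition.

The drug-pathway layer is the projection of the drug-target and
target-pathway layers through shared targets; the pathway-disease layer
comes straight from annotation; mechanism subnetworks pull out, for one
disease pathway, the drugs and in-pathway targets with their interaction
edges.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

from .annotations import AnnotationMap
from .network import BipartiteNetwork

__all__ = [
    "project_drug_pathway",
    "build_pathway_disease",
    "bipartite_mean_degrees",
    "extract_mechanism",
]

logger = logging.getLogger("netpharm")


def project_drug_pathway(
    dt: BipartiteNetwork, tp: BipartiteNetwork
) -> BipartiteNetwork:
    """Compose drug-target and target-pathway layers through shared targets.

    Edge (drug, pathway) exists iff some target links the two; its weight is
    the number of such shared targets.  Degree statistics downstream use the
    unweighted projection; the weight is carried as an edge attribute only.
    A disjoint target namespace yields an empty network with a warning.
    """
    shared = set(dt.right) & set(tp.left)
    if not shared and dt.n_edges and tp.n_edges:
        logger.warning("project\twarning=disjoint-target-namespaces")
    weights: dict[tuple[str, str], int] = {}
    for d, t in dt.edges:
        if t not in shared:
            continue
        for p in tp.neighbors(t):
            weights[(d, p)] = weights.get((d, p), 0) + 1
    left = sorted({d for d, _ in weights})
    right = sorted({p for _, p in weights})
    return BipartiteNetwork(left, right, weights.keys(), weights)


def build_pathway_disease(
    pathways: Iterable[str],
    pathway_disease: AnnotationMap,
    include_isolated: bool = False,
) -> BipartiteNetwork:
    """Pathway-disease layer restricted to the given pathway set.

    One edge per (pathway, disease) annotation.  Pathways without any
    disease appear as declared isolates only when *include_isolated*.
    """
    pathways = sorted(set(pathways))
    edges = [
        (p, d) for p in pathways for d in sorted(pathway_disease.get(p))
    ]
    left = pathways if include_isolated else sorted({p for p, _ in edges})
    right = sorted({d for _, d in edges})
    return BipartiteNetwork(left, right, edges)


def bipartite_mean_degrees(net: BipartiteNetwork) -> tuple[float, float]:
    """Mean degree of each side over all declared nodes (isolates included).

    An empty side has no mean; NaN is returned for it.
    """
    def _mean(nodes: tuple[str, ...]) -> float:
        if not nodes:
            return math.nan
        return sum(net.degree_of(n) for n in nodes) / len(nodes)

    return _mean(net.left), _mean(net.right)


def extract_mechanism(
    dt: BipartiteNetwork, tp: BipartiteNetwork, pathway_id: str
) -> BipartiteNetwork:
    """Mechanism subnetwork for one disease pathway.

    Contains exactly the targets annotated to *pathway_id* that have at
    least one drug hit, the drugs hitting them, and those drug-target
    edges.  Raises KeyError if the pathway is absent from the
    target-pathway layer.
    """
    if pathway_id not in set(tp.right):
        raise KeyError("pathway %r not present in target-pathway network" % pathway_id)
    in_pathway = tp.neighbors(pathway_id)
    dt_targets = set(dt.right)
    edges = [(d, t) for d, t in dt.edges if t in in_pathway and t in dt_targets]
    left = sorted({d for d, _ in edges})
    right = sorted({t for _, t in edges})
    return BipartiteNetwork(left, right, edges)
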