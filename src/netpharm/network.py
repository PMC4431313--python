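"""Bipartite network container and the node statistics reported per layer.

Every layer of the pipeline (drug-target, target-pathway, drug-pathway,
pathway-disease) is an undirected simple bipartite graph.  The statistics
computed here are the two the analysis relies on — degree and normalized
shortest-path betweenness — plus degree stratification of the molecule side
and the stratum-wise pathway relevance-frequency score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import networkx as nx

from .annotations import AnnotationMap

__all__ = [
    "BipartiteNetwork",
    "DegreeStrata",
    "build_bipartite",
    "degree",
    "betweenness",
    "stratify_by_degree",
    "pathway_relevance_score",
]

logger = logging.getLogger("netpharm")

Side = Literal["left", "right"]


class BipartiteNetwork:
    """Undirected simple bipartite graph with typed sides.

    ``left`` and ``right`` are ordered node sequences (duplicates removed,
    order preserved); isolated nodes may be declared by listing them on a
    side without incident edges.  Edges are unordered-unique (left, right)
    pairs; an optional positive-integer weight per edge is carried for
    projections (number of shared intermediate neighbors).
    """

    __slots__ = ("left", "right", "edges", "weights", "_adj")

    def __init__(
        self,
        left: Iterable[str],
        right: Iterable[str],
        edges: Iterable[tuple[str, str]],
        weights: Mapping[tuple[str, str], int] | None = None,
    ):
        self.left: tuple[str, ...] = tuple(dict.fromkeys(left))
        self.right: tuple[str, ...] = tuple(dict.fromkeys(right))
        lset, rset = set(self.left), set(self.right)
        if any(not n for n in lset | rset):
            raise ValueError("empty node id")
        clash = lset & rset
        if clash:
            raise ValueError(
                "node id(s) %s appear on both sides (namespace collision)"
                % sorted(clash)
            )
        eset = set()
        for a, b in edges:
            if a not in lset:
                raise ValueError("edge endpoint %r not a declared left node" % a)
            if b not in rset:
                raise ValueError("edge endpoint %r not a declared right node" % b)
            eset.add((a, b))
        self.edges: frozenset[tuple[str, str]] = frozenset(eset)
        if weights is not None:
            for e, w in weights.items():
                if tuple(e) not in eset:
                    raise ValueError("weight given for absent edge %r" % (e,))
                if not (isinstance(w, int) and w > 0):
                    raise ValueError("edge weight must be a positive integer")
            self.weights = {tuple(e): int(w) for e, w in weights.items()}
        else:
            self.weights = None
        adj: dict[str, set[str]] = {n: set() for n in self.left + self.right}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        self._adj = adj

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self.left + self.right

    @property
    def n_nodes(self) -> int:
        return len(self.left) + len(self.right)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def side_of(self, node: str) -> Side:
        if node in self._adj:
            return "left" if node in set(self.left) else "right"
        raise KeyError(node)

    def neighbors(self, node: str) -> frozenset[str]:
        return frozenset(self._adj[node])

    def degree_of(self, node: str) -> int:
        return len(self._adj[node])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.left:
            g.add_node(n, side="left", bipartite=0)
        for n in self.right:
            g.add_node(n, side="right", bipartite=1)
        for a, b in sorted(self.edges):
            w = 1 if self.weights is None else self.weights.get((a, b), 1)
            g.add_edge(a, b, weight=w)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            set(self.left) == set(other.left)
            and set(self.right) == set(other.right)
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return "BipartiteNetwork(%d+%d nodes, %d edges)" % (
            len(self.left),
            len(self.right),
            self.n_edges,
        )


def build_bipartite(pairs: Iterable[tuple[str, str]]) -> BipartiteNetwork:
    """Build the bipartite network whose edges are exactly *pairs*.

    Node sets are the edge endpoints (no isolated nodes).  A pair whose two
    ids coincide is rejected: the sides live in distinct namespaces.
    """
    pairs = sorted(set(tuple(p) for p in pairs))
    for a, b in pairs:
        if a == b:
            raise ValueError("pair (%r, %r): left id equals right id" % (a, b))
    left = sorted({a for a, _ in pairs})
    right = sorted({b for _, b in pairs})
    return BipartiteNetwork(left, right, pairs)


def degree(net: BipartiteNetwork) -> dict[str, int]:
    """Neighbor count per node (both sides), including declared isolates."""
    return {n: net.degree_of(n) for n in net.nodes}


def betweenness(net: BipartiteNetwork, normalized: bool = True) -> dict[str, float]:
    """Shortest-path betweenness per node, with fractional credit shared
    over equally short paths.

    When *normalized*, each value is divided by (n-1)(n-2)/2 where n is the
    size of the node's connected component, so values lie in [0, 1];
    components with fewer than three nodes get 0.
    """
    g = net.to_networkx()
    out: dict[str, float] = {n: 0.0 for n in g.nodes}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if normalized and len(comp) < 3:
            continue
        out.update(nx.betweenness_centrality(sub, normalized=normalized))
    return out


@dataclass(frozen=True)
class DegreeStrata:
    """Three-way degree stratification: low = [1, c1], middle = [c1+1, c2],
    high = [c2+1, inf).  Defaults carve the molecule side at 10 and 30,
    the cut points used for the ingredient analysis."""

    c1: int = 10
    c2: int = 30

    def __post_init__(self):
        if not (1 <= self.c1 < self.c2):
            raise ValueError("strata cut points must satisfy 1 <= c1 < c2")

    def label(self, deg: int) -> str:
        if deg < 1:
            raise ValueError("stratum undefined for degree < 1")
        if deg <= self.c1:
            return "low"
        if deg <= self.c2:
            return "middle"
        return "high"


def stratify_by_degree(
    net: BipartiteNetwork, side: Side = "left", strata: DegreeStrata | None = None
) -> dict[str, str]:
    """Map every degree-≥1 node of *side* to its stratum label.

    Declared isolates on that side are excluded (with a logged notice): a
    node with no interactions belongs to no stratum.
    """
    if strata is None:
        strata = DegreeStrata()
    nodes = net.left if side == "left" else net.right
    out: dict[str, str] = {}
    for n in nodes:
        d = net.degree_of(n)
        if d == 0:
            logger.info("stratify\tskipped=%s reason=degree-0", n)
            continue
        out[n] = strata.label(d)
    return out


def pathway_relevance_score(
    hits: Iterable[tuple[str, str]], target_pathway: AnnotationMap
) -> dict[str, float]:
    """Relevance frequency of each pathway within one degree stratum.

    For the stratum's hit set, every (molecule, target, pathway) incidence
    triple — one per pathway annotation of each hit's target — counts once;
    a pathway's score is its triple count divided by the stratum total, so
    scores over pathways with at least one triple form a probability vector.
    Raises if the stratum contributes no annotated interaction.
    """
    counts: dict[str, int] = {}
    total = 0
    for _mol, tgt in set(hits):
        for pw in target_pathway.get(tgt):
            counts[pw] = counts.get(pw, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("no interactions in stratum")
    return {pw: c / total for pw, c in sorted(counts.items())}
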