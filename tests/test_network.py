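"""Bipartite construction, degree, betweenness (vs an exhaustive oracle),
degree strata and the pathway relevance-frequency score."""

import itertools
import random
from collections import deque

import pytest

from netpharm import (
    AnnotationMap,
    BipartiteNetwork,
    DegreeStrata,
    betweenness,
    build_bipartite,
    degree,
    pathway_relevance_score,
    stratify_by_degree,
)


# ---------------------------------------------------------------------------
# independent betweenness oracle: literal enumeration of all shortest paths
# ---------------------------------------------------------------------------

def _bfs(adj, s):
    dist = {s: 0}
    preds = {s: []}
    q = deque([s])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                preds[v] = [u]
                q.append(v)
            elif dist[v] == dist[u] + 1:
                preds[v].append(u)
    return dist, preds


def _all_shortest_paths(preds, s, t):
    if t not in preds:
        return
    stack = [[t]]
    while stack:
        path = stack.pop()
        head = path[-1]
        if head == s:
            yield list(reversed(path))
            continue
        for p in preds[head]:
            stack.append(path + [p])


def oracle_betweenness(nodes, edges):
    """Normalized betweenness by enumerating every shortest path."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    # connected components
    comp_of = {}
    for n in nodes:
        if n in comp_of:
            continue
        dist, _ = _bfs(adj, n)
        for m in dist:
            comp_of[m] = n
    raw = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if comp_of[s] != comp_of[t]:
            continue
        _, preds = _bfs(adj, s)
        paths = list(_all_shortest_paths(preds, s, t))
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                raw[v] += 1.0 / len(paths)
    out = {}
    comp_sizes = {}
    for n in nodes:
        comp_sizes.setdefault(comp_of[n], sum(1 for m in nodes if comp_of[m] == comp_of[n]))
    for n in nodes:
        k = comp_sizes[comp_of[n]]
        out[n] = raw[n] / ((k - 1) * (k - 2) / 2) if k >= 3 else 0.0
    return out


def random_bipartite(rng, max_left=6, max_right=6):
    nl = rng.randint(1, max_left)
    nr = rng.randint(1, max_right)
    left = ["L%d" % i for i in range(nl)]
    right = ["R%d" % i for i in range(nr)]
    edges = [
        (a, b) for a in left for b in right if rng.random() < rng.uniform(0.1, 0.6)
    ]
    return BipartiteNetwork(left, right, edges)


# ---------------------------------------------------------------------------


class TestBuildBipartite:
    def test_small_example(self):
        net = build_bipartite({("d1", "t1"), ("d1", "t2")})
        assert net.n_nodes == 3 and net.n_edges == 2
        assert set(net.left) == {"d1"} and set(net.right) == {"t1", "t2"}

    def test_empty(self):
        net = build_bipartite(set())
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_namespace_collision_rejected(self):
        with pytest.raises(ValueError, match="left id equals right id"):
            build_bipartite({("x", "x")})

    def test_counts_match_input_tallies(self):
        rng = random.Random(3)
        pairs = {
            ("d%d" % rng.randrange(57), "t%d" % rng.randrange(271))
            for _ in range(439)
        }
        net = build_bipartite(pairs)
        assert net.n_edges == len(pairs)
        assert net.n_nodes == len({a for a, _ in pairs} | {b for _, b in pairs})

    def test_parallel_edges_collapse(self):
        net = build_bipartite([("d", "t"), ("d", "t")])
        assert net.n_edges == 1


class TestDegree:
    def test_star_center(self):
        net = build_bipartite({("hub", "t%d" % i) for i in range(5)})
        assert degree(net)["hub"] == 5

    def test_declared_isolate_is_zero(self):
        net = BipartiteNetwork(["a", "iso"], ["b"], [("a", "b")])
        assert degree(net)["iso"] == 0

    def test_handshake_against_recount(self):
        rng = random.Random(5)
        net = random_bipartite(rng, 8, 8)
        deg = degree(net)
        assert sum(deg[n] for n in net.left) == net.n_edges
        assert sum(deg[n] for n in net.right) == net.n_edges
        recount = {n: 0 for n in net.nodes}
        for a, b in net.edges:
            recount[a] += 1
            recount[b] += 1
        assert deg == recount


class TestBetweenness:
    def test_path_middle_node_is_one(self):
        net = BipartiteNetwork(["B"], ["A", "C"], [("B", "A"), ("B", "C")])
        assert betweenness(net)["B"] == pytest.approx(1.0)

    def test_leaves_are_zero(self):
        net = BipartiteNetwork(["B"], ["A", "C"], [("B", "A"), ("B", "C")])
        b = betweenness(net)
        assert b["A"] == 0.0 and b["C"] == 0.0

    def test_four_cycle_all_one_sixth(self):
        net = BipartiteNetwork(
            ["L1", "L2"], ["R1", "R2"],
            [("L1", "R1"), ("L1", "R2"), ("L2", "R1"), ("L2", "R2")],
        )
        b = betweenness(net)
        for v in b.values():
            assert v == pytest.approx(1 / 6, abs=1e-12)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = random.Random(2024)
        for _ in range(25):
            net = random_bipartite(rng)  # <= 12 nodes
            got = betweenness(net, normalized=True)
            want = oracle_betweenness(list(net.nodes), list(net.edges))
            for n in net.nodes:
                assert got[n] == pytest.approx(want[n], abs=1e-12)

    def test_values_in_unit_interval(self):
        rng = random.Random(99)
        net = random_bipartite(rng, 8, 8)
        for v in betweenness(net).values():
            assert 0.0 <= v <= 1.0


class TestStrata:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            DegreeStrata(30, 10)
        with pytest.raises(ValueError):
            DegreeStrata(0, 30)

    @pytest.mark.parametrize(
        "deg,label",
        [(62, "high"), (40, "high"), (31, "high"), (30, "middle"),
         (11, "middle"), (10, "low"), (1, "low")],
    )
    def test_default_cutpoints(self, deg, label):
        assert DegreeStrata().label(deg) == label

    def test_reported_degree_sequence_assignment(self):
        # eleven ingredient degrees -> 4 high, 6 middle, 1 low
        degrees = [62, 40, 34, 32, 22, 18, 16, 16, 14, 12, 10]
        strata = DegreeStrata()
        labels = [strata.label(d) for d in degrees]
        assert labels.count("high") == 4
        assert labels.count("middle") == 6
        assert labels.count("low") == 1

    def test_partition_is_total_and_isolates_excluded(self):
        pairs = {("d%d" % i, "t%d" % j) for i in range(4) for j in range(i + 1)}
        pairs = {p for p in pairs}
        net = build_bipartite({p for p in pairs if p[0] != "d0"})
        # declare an isolate explicitly
        net = BipartiteNetwork(list(net.left) + ["iso"], net.right, net.edges)
        mapping = stratify_by_degree(net, "left", DegreeStrata(1, 2))
        assert "iso" not in mapping
        assert set(mapping) == {n for n in net.left if net.degree_of(n) > 0}


class TestRelevanceScore:
    def test_single_pathway_scores_one(self):
        tp = AnnotationMap("tp", {"t1": {"p"}, "t2": {"p"}})
        scores = pathway_relevance_score({("m", "t1"), ("m", "t2")}, tp)
        assert scores == {"p": pytest.approx(1.0)}

    def test_three_to_one_split(self):
        tp = AnnotationMap("tp", {"t1": {"pA"}, "t2": {"pA"}, "t3": {"pA", "pB"}})
        hits = {("m1", "t1"), ("m1", "t2"), ("m2", "t3")}
        scores = pathway_relevance_score(hits, tp)
        assert scores["pA"] == pytest.approx(0.75)
        assert scores["pB"] == pytest.approx(0.25)

    def test_probability_vector(self):
        tp = AnnotationMap("tp", {"t%d" % i: {"p%d" % (i % 3), "p9"} for i in range(7)})
        hits = {("m%d" % (i % 2), "t%d" % i) for i in range(7)}
        scores = pathway_relevance_score(hits, tp)
        assert sum(scores.values()) == pytest.approx(1.0)
        assert all(s > 0 for s in scores.values())

    def test_invariant_under_molecule_relabeling(self):
        tp = AnnotationMap("tp", {"t1": {"pA", "pB"}, "t2": {"pB"}})
        hits = {("m1", "t1"), ("m2", "t2")}
        relabeled = {("zz1", "t1"), ("zz2", "t2")}
        assert pathway_relevance_score(hits, tp) == pathway_relevance_score(relabeled, tp)

    def test_empty_stratum_is_an_error(self):
        tp = AnnotationMap("tp", {"t1": {"p"}})
        with pytest.raises(ValueError, match="no interactions in stratum"):
            pathway_relevance_score(set(), tp)

    def test_merged_strata_equal_triple_weighted_mixture(self):
        tp = AnnotationMap(
            "tp",
            {"t%d" % i: {"p%d" % (i % 4)} | ({"p0"} if i % 2 else set()) for i in range(10)},
        )
        hits_a = {("a%d" % i, "t%d" % i) for i in range(5)}
        hits_b = {("b%d" % i, "t%d" % (i + 5)) for i in range(5)}
        sa = pathway_relevance_score(hits_a, tp)
        sb = pathway_relevance_score(hits_b, tp)
        merged = pathway_relevance_score(hits_a | hits_b, tp)
        ta = sum(len(tp.get(t)) for _, t in hits_a)
        tb = sum(len(tp.get(t)) for _, t in hits_b)
        for p in merged:
            mix = (ta * sa.get(p, 0.0) + tb * sb.get(p, 0.0)) / (ta + tb)
            assert merged[p] == pytest.approx(mix, abs=1e-12)
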