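"""Centralities and global topology statistics against independent oracles."""

import networkx as nx
import pytest

from netpharm.metrics import (
    betweenness,
    bipartite_density,
    centroid_values,
    eccentricity,
    node_metrics,
    reciprocal_eccentricity,
    summarize,
    summary_from_counts,
)
from conftest import random_connected_graph


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration: for every unordered pair,
    list ALL shortest paths and award fractional credit to interior nodes."""
    btw = {v: 0.0 for v in g}
    nodes = list(g)
    for i, s in enumerate(nodes):
        dist = nx.single_source_shortest_path_length(g, s)

        def shortest_paths(t):
            if t == s:
                return [[s]]
            return [p + [t]
                    for u in g.neighbors(t)
                    if u in dist and dist[u] == dist[t] - 1
                    for p in shortest_paths(u)]

        for t in nodes[i + 1:]:
            if t not in dist:
                continue
            paths = shortest_paths(t)
            for p in paths:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(paths)
    return btw


def brute_centroid(g: nx.Graph) -> dict:
    """Direct CentiScaPe definition with explicit u != v, w exclusion."""
    d = dict(nx.all_pairs_shortest_path_length(g))
    inf = float("inf")

    def dd(a, b):
        return d[a].get(b, inf)

    out = {}
    for v in g:
        best = None
        for w in g:
            if w == v:
                continue
            closer_v = sum(1 for u in g if u not in (v, w)
                           and dd(u, v) < dd(u, w))
            closer_w = sum(1 for u in g if u not in (v, w)
                           and dd(u, w) < dd(u, v))
            f = closer_v - closer_w
            best = f if best is None else min(best, f)
        out[v] = best if best is not None else 0
    return out


# ---------------------------------------------------------------------------
# small closed-form cases
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("leaves,expected", [(4, 6.0), (5, 10.0)])
def test_star_center_betweenness_counts_leaf_pairs(leaves, expected):
    g = nx.star_graph(leaves)  # node 0 is the center
    btw = betweenness(g)
    assert btw[0] == pytest.approx(expected)  # C(leaves, 2)
    assert all(btw[v] == 0 for v in g if v != 0)


def test_path_eccentricities():
    g = nx.path_graph(3)  # a - b - c
    ecc = eccentricity(g)
    assert ecc[1] == 1 and ecc[0] == 2 and ecc[2] == 2


def test_reciprocal_eccentricity_variant():
    g = nx.path_graph(3)
    rec = reciprocal_eccentricity(g)
    assert rec[0] == pytest.approx(0.5)
    assert rec[1] == pytest.approx(1.0)


def test_betweenness_matches_brute_force_enumeration(rng):
    """Brandes accumulation equals exhaustive all-shortest-paths counting
    on 200 random graphs of at most 12 nodes."""
    for _ in range(200):
        g = random_connected_graph(rng)
        fast = betweenness(g)
        slow = brute_betweenness(g)
        for v in g:
            assert fast[v] == pytest.approx(slow[v], abs=1e-9)


def test_centroid_matches_direct_definition(rng):
    for _ in range(40):
        g = random_connected_graph(rng)
        assert centroid_values(g) == brute_centroid(g)


def test_centroid_of_star_center_dominates():
    g = nx.star_graph(5)
    cen = centroid_values(g)
    assert cen[0] == max(cen.values())


# ---------------------------------------------------------------------------
# global summaries
# ---------------------------------------------------------------------------

def test_candidate_network_closed_forms():
    """Published candidate-stage graph size (478 nodes, 9220 edges)."""
    s = summary_from_counts(478, 9220)
    assert round(s["avg_degree"], 3) == 38.577
    assert round(s["density"], 3) == 0.081
    assert s["n_shortest_paths"] == 228006


def test_validated_network_closed_forms():
    """Published validated-stage graph (126 nodes, 735 edges, max degree 51)."""
    s = summary_from_counts(126, 735, k_max=51)
    assert round(s["avg_degree"], 3) == 11.667
    assert round(s["density"], 3) == 0.093
    assert round(s["centralization"], 3) == 0.320


def test_complete_graph_is_dense_homogeneous_uncentralized():
    s = summarize(nx.complete_graph(5))
    assert s.density == pytest.approx(1.0)
    assert s.heterogeneity == pytest.approx(0.0)
    assert s.centralization == pytest.approx(0.0)


@pytest.mark.parametrize("g", [nx.cycle_graph(7), nx.complete_graph(6)])
def test_centralization_zero_on_regular_graphs(g):
    assert summarize(g).centralization == pytest.approx(0.0)


@pytest.mark.parametrize("n", [5, 9, 30])
def test_centralization_one_on_stars(n):
    assert summarize(nx.star_graph(n)).centralization == pytest.approx(1.0)


def test_summarize_consistent_with_closed_forms(rng):
    for _ in range(10):
        g = random_connected_graph(rng)
        s = summarize(g)
        c = summary_from_counts(s.n_nodes, s.n_edges,
                                k_max=max(d for _, d in g.degree()))
        assert s.avg_degree == pytest.approx(c["avg_degree"])
        assert s.density == pytest.approx(c["density"])
        assert s.n_shortest_paths == c["n_shortest_paths"]
        if s.n_nodes >= 3:
            assert s.centralization == pytest.approx(c["centralization"])
        # handshake
        assert sum(d for _, d in g.degree()) == 2 * s.n_edges


def test_disconnected_pairs_excluded_from_path_statistics():
    g = nx.Graph([("a", "b"), ("c", "d")])
    for n in g:
        g.nodes[n]["partition"] = "compound" if n in "ac" else "target"
    s = summarize(g)
    assert s.n_shortest_paths == 4  # two reachable ordered pairs per edge
    assert s.characteristic_path_length == pytest.approx(1.0)


def test_node_metrics_table_shape(bundle):
    from netpharm.networks import build_compound_target
    inter = [h for h in bundle.hits if h.fit_score >= 3.0][:120]
    g = build_compound_target(inter)
    nm = node_metrics(g)
    assert set(nm.columns) == {"node_id", "partition", "degree",
                               "betweenness", "eccentricity", "centroid"}
    assert len(nm) == g.number_of_nodes()
    assert (nm["degree"] == [g.degree[n] for n in nm["node_id"]]).all()


def test_bipartite_density_uses_partition_sizes():
    g = nx.Graph()
    g.add_node("c1", partition="compound")
    g.add_node("c2", partition="compound")
    g.add_node("t1", partition="target")
    g.add_edges_from([("c1", "t1"), ("c2", "t1")])
    assert bipartite_density(g) == pytest.approx(1.0)
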