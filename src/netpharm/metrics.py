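"""Node centralities and global topology statistics.

The metric set mirrors the Cytoscape NetworkAnalyzer / CentiScaPe
conventions used for drug-target network analysis:

* degree, plus *unnormalized* shortest-path betweenness (Brandes algorithm,
  unordered source-sink pairs counted once, endpoints excluded, fractional
  credit across equal-length shortest paths);
* eccentricity as the plain maximum hop distance to any reachable node
  (CentiScaPe's reciprocal variant is available separately);
* the CentiScaPe centroid value
  ``centroid(v) = min over w != v of (#{u: d(u,v) < d(u,w)} - #{u: d(u,w) < d(u,v)})``;
* global summary: average degree, density, degree centralization,
  characteristic path length, count of reachable ordered pairs, degree
  heterogeneity (coefficient of variation), diameter.

Density and centralization use the plain unipartite denominators even on
bipartite graphs, matching the reported convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkSummary",
    "node_metrics",
    "betweenness",
    "eccentricity",
    "reciprocal_eccentricity",
    "centroid_values",
    "summarize",
    "summary_from_counts",
    "bipartite_density",
]


def betweenness(graph: nx.Graph, normalized: bool = False) -> dict:
    """Brandes betweenness on unweighted shortest paths (unnormalized by
    default, matching published magnitudes on modest graphs)."""
    return nx.betweenness_centrality(graph, normalized=normalized)


def _distance_matrix(graph: nx.Graph) -> tuple[list, np.ndarray]:
    """All-pairs unweighted distances; unreachable pairs are +inf."""
    nodes = list(graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        i = index[src]
        for dst, dist in lengths.items():
            d[i, index[dst]] = dist
    return nodes, d


def eccentricity(graph: nx.Graph) -> dict:
    """Max hop distance to any *reachable* node (finite on every component)."""
    ecc: dict = {}
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        ecc[src] = max(lengths.values())
    return ecc


def reciprocal_eccentricity(graph: nx.Graph) -> dict:
    """CentiScaPe's 1/eccentricity variant (isolated nodes report 0)."""
    return {v: (1.0 / e if e > 0 else 0.0) for v, e in eccentricity(graph).items()}


def centroid_values(graph: nx.Graph) -> dict:
    """CentiScaPe centroid value per node.

    For each competing node w, count how many nodes are strictly closer to v
    than to w and vice versa; the centroid value is the minimum difference
    over all w.  Nodes u = v and u = w contribute +1 and -1 and cancel, so
    the counts run over all nodes.
    """
    nodes, d = _distance_matrix(graph)
    n = len(nodes)
    if n < 2:
        return {v: 0 for v in nodes}
    out = {}
    for j, v in enumerate(nodes):
        col = d[:, j][:, None]  # d(u, v) over u
        closer_v = (col < d).sum(axis=0)  # per w: #{u: d(u,v) < d(u,w)}
        closer_w = (col > d).sum(axis=0)
        f = closer_v - closer_w
        f[j] = np.iinfo(np.int64).max  # exclude w = v from the min
        out[v] = int(f.min())
    return out


def node_metrics(graph: nx.Graph, normalized_betweenness: bool = False) -> pd.DataFrame:
    """Per-node degree / betweenness / eccentricity / centroid table."""
    if graph.number_of_nodes() == 0:
        raise ValueError("node_metrics requires a non-empty graph")
    deg = dict(graph.degree())
    btw = betweenness(graph, normalized=normalized_betweenness)
    ecc = eccentricity(graph)
    cen = centroid_values(graph)
    rows = [
        {
            "node_id": v,
            "partition": graph.nodes[v].get("partition", ""),
            "degree": deg[v],
            "betweenness": btw[v],
            "eccentricity": ecc[v],
            "centroid": cen[v],
        }
        for v in graph.nodes()
    ]
    return pd.DataFrame(rows)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    centralization: float | None
    characteristic_path_length: float
    n_shortest_paths: int
    heterogeneity: float
    diameter: int
    avg_eccentricity: float
    avg_centroid: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def summary_from_counts(
    n_nodes: int, n_edges: int, k_max: int | None = None,
    connected: bool = True,
) -> dict:
    """Closed-form global statistics that depend only on node/edge counts
    (and the maximum degree, for centralization).

    For a connected graph the number of reachable ordered pairs is
    n*(n-1).
    """
    if n_nodes < 1:
        raise ValueError("need at least one node")
    avg_degree = 2.0 * n_edges / n_nodes
    density = (
        2.0 * n_edges / (n_nodes * (n_nodes - 1)) if n_nodes > 1 else 0.0
    )
    out = {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "avg_degree": avg_degree,
        "density": density,
        "n_shortest_paths": n_nodes * (n_nodes - 1) if connected else None,
        "centralization": None,
    }
    if k_max is not None and n_nodes >= 3:
        out["centralization"] = (n_nodes / (n_nodes - 2.0)) * (
            k_max / (n_nodes - 1.0) - density
        )
    return out


def bipartite_density(graph: nx.Graph) -> float:
    """Density with the bipartite denominator n1*n2 (clearly-named variant;
    the default summary uses the unipartite denominator)."""
    parts: dict[str, int] = {}
    for _, data in graph.nodes(data=True):
        p = data.get("partition", "")
        parts[p] = parts.get(p, 0) + 1
    if len(parts) != 2:
        raise ValueError("bipartite_density requires exactly two partitions")
    n1, n2 = parts.values()
    return graph.number_of_edges() / (n1 * n2)


def summarize(graph: nx.Graph) -> NetworkSummary:
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("summarize requires a non-empty graph")
    m = graph.number_of_edges()
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    avg_degree = 2.0 * m / n
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    centralization = None
    if n >= 3:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)

    # path statistics over reachable ordered pairs only
    total_dist = 0
    n_pairs = 0
    diameter = 0
    ecc_values = []
    for _, lengths in nx.all_pairs_shortest_path_length(graph):
        finite = [d for d in lengths.values() if d > 0]
        total_dist += sum(finite)
        n_pairs += len(finite)
        ecc_values.append(max(lengths.values()))
        diameter = max(diameter, ecc_values[-1])
    cpl = total_dist / n_pairs if n_pairs else 0.0

    mean_deg = degrees.mean()
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    centroids = list(centroid_values(graph).values())
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        avg_degree=avg_degree,
        density=density,
        centralization=centralization,
        characteristic_path_length=cpl,
        n_shortest_paths=n_pairs,
        heterogeneity=heterogeneity,
        diameter=int(diameter),
        avg_eccentricity=float(np.mean(ecc_values)),
        avg_centroid=float(np.mean(centroids)),
    )
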