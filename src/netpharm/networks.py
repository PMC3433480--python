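"""Construction and serialization of the four bipartite association networks.

All four graphs are undirected, unweighted and bipartite:

* compound - candidate target (C-cT) and compound - potential target (C-T),
  built from interaction records at the two cascade stages;
* compound - pathway (C-P), linking a compound to every pathway containing
  at least one of its validated targets;
* target - disease (T-D), from per-target disease annotations.

Nodes carry a ``partition`` attribute (compound/target/pathway/disease),
a display name, and herb attribution for compounds.  Nodes with zero edges
are excluded from the built graphs.  Graphs are plain ``networkx.Graph``
objects so the whole networkx toolbox applies.
"""

from __future__ import annotations

import csv

import networkx as nx

from .screen_targets import InteractionRecord

__all__ = [
    "PARTITIONS",
    "GraphError",
    "build_compound_target",
    "build_compound_pathway",
    "build_target_disease",
    "validate_graph",
    "export_graph",
    "load_graph",
    "normalize_disease",
]

PARTITIONS = ("compound", "target", "pathway", "disease")

# SIF interaction tokens per edge type
_SIF_TOKENS = {
    frozenset({"compound", "target"}): "ct",
    frozenset({"compound", "pathway"}): "cp",
    frozenset({"target", "disease"}): "td",
}


class GraphError(ValueError):
    pass


def validate_graph(graph: nx.Graph) -> None:
    """Enforce the labeled-graph invariants: known partition labels, no
    self-loops, and every edge joining two distinct partitions."""
    for node, data in graph.nodes(data=True):
        if data.get("partition") not in PARTITIONS:
            raise GraphError(f"node {node!r}: missing/unknown partition label")
    for u, v in graph.edges():
        if u == v:
            raise GraphError(f"self-loop at {u!r}")
        pu = graph.nodes[u]["partition"]
        pv = graph.nodes[v]["partition"]
        if pu == pv:
            raise GraphError(f"edge ({u!r}, {v!r}) joins two {pu!r} nodes")


def _add_node(graph, node_id, partition, names=None, herbs=None):
    attrs = {"partition": partition}
    if names and node_id in names:
        attrs["name"] = names[node_id]
    if herbs and node_id in herbs:
        attrs["herbs"] = ";".join(sorted(herbs[node_id]))
    graph.add_node(node_id, **attrs)


def build_compound_target(
    interactions: list[InteractionRecord],
    compound_names: dict[str, str] | None = None,
    target_names: dict[str, str] | None = None,
    compound_herbs: dict[str, frozenset] | None = None,
    known_compounds: set[str] | None = None,
    known_targets: set[str] | None = None,
) -> nx.Graph:
    """Bipartite compound-target graph: one node per id appearing in at
    least one interaction, one edge per distinct pair (duplicates collapse).

    When node tables are supplied (``known_compounds``/``known_targets``),
    a dangling interaction endpoint is an error.
    """
    g = nx.Graph()
    for rec in interactions:
        if known_compounds is not None and rec.compound_id not in known_compounds:
            raise GraphError(f"unknown compound {rec.compound_id!r}")
        if known_targets is not None and rec.target_id not in known_targets:
            raise GraphError(f"unknown target {rec.target_id!r}")
        if rec.compound_id == rec.target_id:
            raise GraphError(f"compound and target share id {rec.compound_id!r}")
        _add_node(g, rec.compound_id, "compound", compound_names, compound_herbs)
        _add_node(g, rec.target_id, "target", target_names)
        g.add_edge(rec.compound_id, rec.target_id)
    validate_graph(g)
    return g


def build_compound_pathway(
    interactions: list[InteractionRecord],
    target_pathways: dict[str, frozenset | set],
    compound_herbs: dict[str, frozenset] | None = None,
) -> nx.Graph:
    """Bipartite compound-pathway graph.

    A compound links to a pathway iff one of its (validated) targets belongs
    to it; compounds hitting no pathway are absent from the graph.  Several
    targets in the same pathway still yield a single edge.
    """
    missing = sorted(
        {r.target_id for r in interactions} - set(target_pathways)
    )
    if missing:
        raise GraphError(f"targets without pathway annotation: {missing}")
    g = nx.Graph()
    for rec in interactions:
        for pw in target_pathways[rec.target_id]:
            _add_node(g, rec.compound_id, "compound", None, compound_herbs)
            _add_node(g, pw, "pathway")
            g.add_edge(rec.compound_id, pw)
    validate_graph(g)
    return g


def normalize_disease(name: str) -> str:
    """Conservative disease-name normalization: trim + case-fold only."""
    return " ".join(str(name).split()).casefold()


def build_target_disease(targets) -> nx.Graph:
    """Bipartite target-disease graph from TargetRecord annotations.

    Disease names are normalized (whitespace/case) before node creation; a
    target with an empty disease list contributes no node.
    """
    g = nx.Graph()
    records = targets.values() if hasattr(targets, "values") else targets
    for rec in records:
        for disease in rec.diseases:
            d = normalize_disease(disease)
            if not d:
                continue
            g.add_node(rec.target_id, partition="target",
                       name=rec.short_name or rec.target_id)
            g.add_node(d, partition="disease")
            g.add_edge(rec.target_id, d)
    validate_graph(g)
    return g


def export_graph(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Write a graph as SIF, GraphML or edge-list TSV.

    GraphML and TSV round-trip through :func:`load_graph`; SIF is a
    write-only interchange format (it carries no node attributes).
    """
    validate_graph(graph)
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "sif":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for u, v in sorted(graph.edges()):
                token = _SIF_TOKENS.get(
                    frozenset({graph.nodes[u]["partition"],
                               graph.nodes[v]["partition"]}), "link")
                w.writerow([u, token, v])
    elif format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["source_id", "source_partition", "target_id",
                        "target_partition"])
            for u, v in sorted(graph.edges()):
                w.writerow([u, graph.nodes[u]["partition"],
                            v, graph.nodes[v]["partition"]])
    else:
        raise GraphError(f"unknown export format {format!r}")


def load_graph(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)
    elif format == "tsv":
        g = nx.Graph()
        with open(path, newline="") as fh:
            r = csv.reader(fh, delimiter="\t")
            header = next(r)
            if header[:1] != ["source_id"]:
                raise GraphError("not an edge-list TSV written by export_graph")
            for u, pu, v, pv in r:
                g.add_node(u, partition=pu)
                g.add_node(v, partition=pv)
                g.add_edge(u, v)
    else:
        raise GraphError(f"unknown import format {format!r}")
    validate_graph(g)
    return g
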