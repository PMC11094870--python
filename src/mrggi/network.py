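"""Directed interaction graph assembly, clustering and hub filtering.

Non-independent interaction calls become arcs of a directed multigraph
(a bidirectional call contributes one arc in each direction). Community
detection runs Louvain modularity optimization on the undirected unweighted
projection; degree centrality is counted on the directed multigraph, so
reciprocal arcs count twice.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .pairs import InteractionCall

__all__ = [
    "build_graph",
    "louvain_clusters",
    "degree_filter",
    "graph_to_edge_frame",
    "write_graph",
    "clusters_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEGREE = 3


def build_graph(calls: Sequence[InteractionCall]) -> nx.MultiDiGraph:
    """Directed multigraph of all non-independent calls.

    Arc attributes carry the IVW effect and adjusted p-value of that
    direction. Nodes are exactly the genes incident to at least one arc.
    Duplicate unordered pairs are an input error.
    """
    seen = set()
    graph = nx.MultiDiGraph()
    for call in calls:
        key = (call.pair.gene_i, call.pair.gene_j)
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        if call.scenario in ("i_to_j", "bidirectional"):
            graph.add_edge(call.pair.gene_i, call.pair.gene_j,
                           beta_hat=call.est_ij.beta_hat, p_adj=call.p_ij_adj)
        if call.scenario in ("j_to_i", "bidirectional"):
            graph.add_edge(call.pair.gene_j, call.pair.gene_i,
                           beta_hat=call.est_ji.beta_hat, p_adj=call.p_ji_adj)
    return graph


def louvain_clusters(graph: nx.MultiDiGraph, seed: int = 0) -> dict[str, int]:
    """Louvain community labels on the undirected unweighted projection.

    Parallel and reciprocal arcs collapse to single undirected edges before
    modularity optimization (resolution 1.0). Labels are contiguous integers
    from 1, ordered by decreasing community size (ties by smallest member
    id), and deterministic for a fixed seed.
    """
    if graph.number_of_nodes() == 0:
        return {}
    undirected = nx.Graph()
    undirected.add_nodes_from(graph.nodes)
    undirected.add_edges_from((u, v) for u, v, _ in graph.edges(keys=True) if u != v)
    communities = nx.community.louvain_communities(undirected, seed=seed)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {gene: label for label, members in enumerate(ordered, start=1) for gene in sorted(members)}


def degree_filter(
    graph: nx.MultiDiGraph,
    clusters: Mapping[str, int],
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> dict[int, list[str]]:
    """Per-cluster gene lists retaining only genes of degree >= min_degree.

    Degree is in-degree plus out-degree on the directed multigraph; each arc
    of a reciprocal pair counts.
    """
    missing = set(graph.nodes) - set(clusters)
    if missing:
        raise ValueError(f"clusters must cover all nodes; missing {sorted(missing)[:5]}")
    retained: dict[int, list[str]] = {label: [] for label in sorted(set(clusters.values()))}
    for gene in sorted(graph.nodes):
        if graph.in_degree(gene) + graph.out_degree(gene) >= min_degree:
            retained[clusters[gene]].append(gene)
    return retained


def graph_to_edge_frame(graph: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "beta_hat": d.get("beta_hat"), "p_adj": d.get("p_adj")}
        for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "beta_hat", "p_adj"])


def write_graph(graph: nx.MultiDiGraph, path, fmt: str = "tsv") -> None:
    """Write the graph as an edge-list TSV, GraphML, or SIF file."""
    path = str(path)
    if fmt == "tsv":
        graph_to_edge_frame(graph).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges(keys=False)):
                fh.write(f"{u}\tregulates\t{v}\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def clusters_to_frame(
    graph: nx.MultiDiGraph,
    clusters: Mapping[str, int],
    min_degree: int = DEFAULT_MIN_DEGREE,
) -> pd.DataFrame:
    """Cluster assignment table: gene_id, cluster, degree, retained_flag."""
    retained = degree_filter(graph, clusters, min_degree)
    keep = {g for genes in retained.values() for g in genes}
    rows = [
        {
            "gene_id": gene,
            "cluster": clusters[gene],
            "degree": graph.in_degree(gene) + graph.out_degree(gene),
            "retained_flag": gene in keep,
        }
        for gene in sorted(graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "degree", "retained_flag"])
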