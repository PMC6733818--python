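"""Inter-cluster similarity network, minimum spanning tree and exports.

Clusters become nodes; every pair of cluster representatives is compared by
the best local (Smith-Waterman) alignment over both strands, giving a
percent similarity edge.  The minimum spanning tree over distance =
100 - similarity summarises the network; node composition quantifies how
strongly species intermix within clusters (the concerted-evolution
diagnostic: homogenising drive predicts species-pure, well-separated
clusters, a conserved satellite predicts intermingled ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from ._align import local_best_hit
from .errors import SatconnectError
from .satcluster import Cluster


@dataclass(frozen=True)
class GraphEdge:
    a: int
    b: int
    similarity: float  # percent, in [0, 100]

    @property
    def distance(self) -> float:
        return 100.0 - self.similarity


@dataclass
class ClusterGraph:
    """Nodes (clusters), all pairwise similarity edges, and the MST subset."""

    nodes: list[Cluster]
    edges: list[GraphEdge] = field(default_factory=list)
    mst_edges: list[GraphEdge] = field(default_factory=list)

    @property
    def mixing(self) -> float:
        multi = sum(1 for c in self.nodes if c.n_sources >= 2)
        return multi / len(self.nodes) if self.nodes else 0.0


def cluster_similarity(a: Cluster, b: Cluster) -> float:
    """Percent similarity of two cluster representatives.

    Best local alignment over both strands (match +1, mismatch -1, gap open
    -2, extension -1); similarity = 100 * matches / local alignment columns.
    """
    if not a.representative.bases or not b.representative.bases:
        raise SatconnectError("empty representative")
    hit = local_best_hit(a.representative.bases, b.representative.bases)
    if hit.columns == 0:
        return 0.0
    return 100.0 * hit.matches / hit.columns


def build_graph(clusters: Sequence[Cluster]) -> ClusterGraph:
    """Complete similarity graph over all cluster pairs, plus its MST."""
    nodes = list(clusters)
    edges: list[GraphEdge] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            sim = cluster_similarity(nodes[i], nodes[j])
            edges.append(GraphEdge(nodes[i].id, nodes[j].id, sim))
    graph = ClusterGraph(nodes=nodes, edges=edges)
    if len(nodes) > 1:
        graph.mst_edges = build_mst([c.id for c in nodes], edges)
    return graph


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_mst(node_ids: Sequence[int], edges: Sequence[GraphEdge]) -> list[GraphEdge]:
    """Kruskal MST over distance = 100 - similarity.

    Deterministic tie-break: edges of equal distance are taken in order of
    (smaller node id, larger node id).  Raises when the graph is
    disconnected, listing the components.
    """
    ordered = sorted(
        edges,
        key=lambda e: (e.distance, min(e.a, e.b), max(e.a, e.b)),
    )
    uf = _UnionFind(node_ids)
    mst: list[GraphEdge] = []
    for edge in ordered:
        if uf.union(edge.a, edge.b):
            mst.append(edge)
    if len(mst) != len(node_ids) - 1:
        g = nx.Graph()
        g.add_nodes_from(node_ids)
        g.add_edges_from((e.a, e.b) for e in edges)
        components = [sorted(c) for c in nx.connected_components(g)]
        raise SatconnectError(
            f"similarity graph is disconnected; components: {components}"
        )
    return mst


def mixing_summary(graph: ClusterGraph) -> tuple[float, float]:
    """(fraction of multi-source nodes, size-weighted mean Shannon's H)."""
    if not graph.nodes:
        raise SatconnectError("empty graph")
    multi = sum(1 for c in graph.nodes if c.n_sources >= 2)
    total_reads = sum(c.raw_count for c in graph.nodes)
    if total_reads == 0:
        weighted_h = 0.0
    else:
        weighted_h = sum(
            (c.shannon_h or 0.0) * c.raw_count for c in graph.nodes
        ) / total_reads
    return (multi / len(graph.nodes), weighted_h)


def _to_networkx(graph: ClusterGraph) -> nx.Graph:
    g = nx.Graph()
    mst_set = {(min(e.a, e.b), max(e.a, e.b)) for e in graph.mst_edges}
    for cluster in graph.nodes:
        attrs = {
            "size": cluster.raw_count,
            "shannon_h": float(cluster.shannon_h or 0.0),
            "representative": cluster.representative.id,
        }
        for source, count in sorted(cluster.composition.items()):
            attrs[f"count_{source}"] = count
        g.add_node(cluster.id, **attrs)
    for edge in graph.edges:
        key = (min(edge.a, edge.b), max(edge.a, edge.b))
        g.add_edge(edge.a, edge.b,
                   similarity=float(edge.similarity),
                   in_mst=key in mst_set)
    return g


def export_graph(graph: ClusterGraph, path: str | Path, format: str = "graphml") -> None:
    """Write the graph as GraphML or DOT with node/edge attributes."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_to_networkx(graph), path)
    elif format == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _dot_escape(value) -> str:
    return '"' + str(value).replace('"', r"\"") + '"'


def _write_dot(graph: ClusterGraph, path: Path) -> None:
    mst_set = {(min(e.a, e.b), max(e.a, e.b)) for e in graph.mst_edges}
    lines = ["graph clusters {"]
    for cluster in sorted(graph.nodes, key=lambda c: c.id):
        attrs = [
            f"size={cluster.raw_count}",
            f"shannon_h={cluster.shannon_h or 0.0:.6f}",
            f"representative={_dot_escape(cluster.representative.id)}",
        ]
        pie = ";".join(
            f"{source}:{count}" for source, count in sorted(cluster.composition.items())
        )
        attrs.append(f"composition={_dot_escape(pie)}")
        lines.append(f"  n{cluster.id} [{', '.join(attrs)}];")
    for edge in sorted(graph.edges, key=lambda e: (min(e.a, e.b), max(e.a, e.b))):
        key = (min(edge.a, edge.b), max(edge.a, edge.b))
        in_mst = "true" if key in mst_set else "false"
        lines.append(
            f"  n{edge.a} -- n{edge.b} "
            f"[similarity={edge.similarity:.4f}, in_mst={in_mst}];"
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
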