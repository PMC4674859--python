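"""Merged gene–pathway interaction network and its topology statistics.

The network is an undirected multigraph whose nodes are Entrez genes and
canonical pathways. Edges come from two sources:

1. text-mined interaction pairs (one edge per unique pair), and
2. curated pathway membership: when a gene node is a member of a pathway
   node according to the pathway database, a ``member_of`` edge is added.

A text-mined edge and a curated membership between the same endpoints
coexist — this is what the "multi-edge node pairs" statistic counts. All
path-based statistics (components, diameter, characteristic path length,
clustering, betweenness) are computed on the simplified graph with parallel
edges collapsed; hub degree counts edge multiplicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .events import CATEGORY_RELATION, InteractionPair
from .normalize import NodeKey
from .standoff import PathwayDB, UsageError, node_label

__all__ = [
    "InteractionNetwork",
    "NetworkStats",
    "RankedNode",
    "build_network",
    "add_curated_edges",
    "compute_stats",
    "rank_hubs",
    "rank_bottlenecks",
    "write_stats_tsv",
]


class InteractionNetwork:
    """Multigraph over typed node keys with relation/origin edge labels."""

    def __init__(self) -> None:
        self.graph = nx.MultiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, key: NodeKey) -> None:
        self.graph.add_node(key)

    def add_edge(self, a: NodeKey, b: NodeKey, relation: str, origin: str) -> None:
        if a == b:
            raise UsageError(f"self-loops are not allowed: {a}")
        if relation == "member_of":
            kinds = {a[0], b[0]}
            if kinds != {"GENE", "PATHWAY"}:
                raise UsageError(
                    f"member_of must connect one gene and one pathway, got {a} -- {b}"
                )
        self.graph.add_edge(a, b, relation=relation, origin=origin)

    # -- inspection -------------------------------------------------------
    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> set[NodeKey]:
        return set(self.graph.nodes)

    def edge_triples(self) -> list[tuple[NodeKey, NodeKey, str]]:
        return [(a, b, data["relation"]) for a, b, data in self.graph.edges(data=True)]

    def edge_multiset(self) -> dict[tuple[frozenset, str], int]:
        counts: dict[tuple[frozenset, str], int] = {}
        for a, b, rel in self.edge_triples():
            k = (frozenset((a, b)), rel)
            counts[k] = counts.get(k, 0) + 1
        return counts

    def edge_multiset_by_pair(self) -> dict[frozenset, int]:
        counts: dict[frozenset, int] = {}
        for a, b, _rel in self.edge_triples():
            k = frozenset((a, b))
            counts[k] = counts.get(k, 0) + 1
        return counts

    def has_member_of_edge(self, gene: NodeKey, pathway: NodeKey) -> bool:
        if not self.graph.has_edge(gene, pathway):
            return False
        return any(
            d["relation"] == "member_of" for d in self.graph[gene][pathway].values()
        )

    def simplified(self) -> nx.Graph:
        """Parallel edges collapsed; node set preserved."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from((a, b) for a, b, _k in self.graph.edges(keys=True))
        return g

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        out.graph = self.graph.copy()
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes() == other.nodes() and self.edge_multiset() == other.edge_multiset()


@dataclass(frozen=True)
class NetworkStats:
    node_count: int
    edge_count: int
    clustering_coefficient: float
    connected_components: int
    diameter: int | None
    characteristic_path_length: float | None
    avg_neighbors: float
    density: float
    multi_edge_node_pairs: int


@dataclass(frozen=True)
class RankedNode:
    node: NodeKey
    score: float
    rank: int


def build_network(pairs: Iterable[InteractionPair]) -> InteractionNetwork:
    """One TEXT_MINED edge per unique pair; nodes are exactly the endpoints."""
    net = InteractionNetwork()
    for pair in sorted(
        pairs, key=lambda p: (str(p.node_a), str(p.node_b), p.category.value)
    ):
        net.add_edge(
            pair.node_a,
            pair.node_b,
            relation=CATEGORY_RELATION[pair.category],
            origin="TEXT_MINED",
        )
    return net


def add_curated_edges(
    net: InteractionNetwork, db: PathwayDB, expand_members: bool = False
) -> InteractionNetwork:
    """Add curated ``member_of`` edges for gene∈pathway membership.

    Default: only for gene and pathway nodes already present. With
    ``expand_members`` the member genes of each present pathway are added
    as new nodes with their membership edges. Idempotent: an existing
    member_of edge between the same endpoints is not duplicated.
    """
    out = net.copy()
    genes = sorted((n for n in out.nodes() if n[0] == "GENE"), key=lambda n: str(n[1]))
    pathways = sorted((n for n in out.nodes() if n[0] == "PATHWAY"), key=lambda n: str(n[1]))
    for pw in pathways:
        rec = db.get(pw[1])  # type: ignore[arg-type]
        if rec is None:
            continue
        if expand_members:
            for gid in sorted(rec.members):
                gene = ("GENE", gid)
                if not out.has_member_of_edge(gene, pw):
                    out.add_edge(gene, pw, relation="member_of", origin="CURATED")
        else:
            for gene in genes:
                if gene[1] in rec.members and not out.has_member_of_edge(gene, pw):
                    out.add_edge(gene, pw, relation="member_of", origin="CURATED")
    return out


def compute_stats(net: InteractionNetwork) -> NetworkStats:
    """Topology statistics in the NetworkAnalyzer conventions.

    Clustering is the mean over all nodes of 2e/(k(k-1)) on the simplified
    graph (nodes with k < 2 contribute 0). Diameter and characteristic path
    length pool shortest paths over connected pairs only, so they stay
    finite on multi-component networks. Density is avg_neighbors/(N-1).
    """
    g = net.simplified()
    n = g.number_of_nodes()
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0, None, None, 0.0, 0.0, 0)

    clustering = nx.average_clustering(g, count_zeros=True) if n > 0 else 0.0
    components = nx.number_connected_components(g)

    diameter: int | None = None
    cpl: float | None = None
    total_len = 0
    total_pairs = 0
    max_len = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, dist in lengths.items():
                if src == dst:
                    continue
                total_len += dist
                total_pairs += 1  # ordered pairs; symmetric, cancels in the mean
                max_len = max(max_len, dist)
    if total_pairs > 0:
        diameter = max_len
        cpl = total_len / total_pairs

    degrees = [g.degree(v) for v in g.nodes]
    avg_neighbors = sum(degrees) / n
    density = avg_neighbors / (n - 1) if n > 1 else 0.0

    multi = sum(1 for count in net.edge_multiset_by_pair().values() if count > 1)
    return NetworkStats(
        node_count=net.node_count,
        edge_count=net.edge_count,
        clustering_coefficient=clustering,
        connected_components=components,
        diameter=diameter,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        density=density,
        multi_edge_node_pairs=multi,
    )


def _node_sort_key(node: NodeKey) -> tuple[str, str]:
    return (node[0], str(node[1]))


def rank_hubs(net: InteractionNetwork, k: int) -> list[RankedNode]:
    """Top-k nodes by degree with edge multiplicity counted.

    Ties are broken by node key ascending, so ranking is deterministic.
    """
    if k < 0:
        raise UsageError("k must be non-negative")
    scored = sorted(
        ((node, net.graph.degree(node)) for node in net.graph.nodes),
        key=lambda item: (-item[1], _node_sort_key(item[0])),
    )
    return [RankedNode(node, float(deg), i + 1) for i, (node, deg) in enumerate(scored[:k])]


def rank_bottlenecks(net: InteractionNetwork, k: int) -> list[RankedNode]:
    """Top-k nodes by unnormalized shortest-path betweenness centrality.

    Betweenness counts the shortest paths passing through a node, with
    fractional credit when several shortest paths tie; parallel edges are
    collapsed first. Ties in score are broken by node key ascending.
    """
    if k < 0:
        raise UsageError("k must be non-negative")
    bc = nx.betweenness_centrality(net.simplified(), normalized=False)
    scored = sorted(bc.items(), key=lambda item: (-item[1], _node_sort_key(item[0])))
    return [RankedNode(node, score, i + 1) for i, (node, score) in enumerate(scored[:k])]


def write_stats_tsv(stats: NetworkStats, path: str | Path) -> Path:
    def fmt(x: object) -> str:
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.6g}" if math.isfinite(x) else "NA"
        return str(x)

    rows = [
        ("Nodes", stats.node_count),
        ("Edges", stats.edge_count),
        ("Clustering coefficient", stats.clustering_coefficient),
        ("Connected components", stats.connected_components),
        ("Network diameter", stats.diameter),
        ("Characteristic path length", stats.characteristic_path_length),
        ("Average number of neighbours", stats.avg_neighbors),
        ("Network density", stats.density),
        ("Multi-edge node pairs", stats.multi_edge_node_pairs),
    ]
    out = Path(path)
    out.write_text("".join(f"{k}\t{fmt(v)}\n" for k, v in rows), encoding="utf-8")
    return out


def hub_table(ranked: list[RankedNode]) -> str:
    return "".join(
        f"{r.rank}\t{node_label(r.node)}\t{r.score:g}\n" for r in ranked
    )
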