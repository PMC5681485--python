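"""MCODE-style molecular-complex detection.

Vertices are weighted by the density of the highest k-core of their closed
neighborhood scaled by that core's k; clusters grow greedily from the
highest-weight unassigned seed, including neighbors whose weight is within
a percentage of the seed's. Cluster score = density x node count, with
density = edges / (n(n-1)/2) on the simple graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["McodeParams", "Cluster", "vertex_weights", "find_clusters", "score_cluster"]


@dataclass
class McodeParams:
    vertex_weight_percentage: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_threshold: float = 0.5
    k_core_min: int = 2
    max_depth: int = 100
    min_cluster_size: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.vertex_weight_percentage <= 1.0):
            raise ValueError("vertex_weight_percentage must lie in [0, 1]")


@dataclass
class Cluster:
    nodes: list[str]
    n_nodes: int
    n_edges: int
    density: float
    score: float
    seed: str
    rank: int = 0

    @staticmethod
    def from_subgraph(sub: nx.Graph, seed: str, rank: int = 0) -> "Cluster":
        n = sub.number_of_nodes()
        e = sub.number_of_edges()
        dens = _density(n, e)
        return Cluster(
            nodes=sorted(sub.nodes), n_nodes=n, n_edges=e,
            density=dens, score=dens * n, seed=seed, rank=rank,
        )


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1) / 2.0)


def score_cluster(sub: nx.Graph) -> float:
    """density x node count (simple-graph maximum n(n-1)/2)."""
    n = sub.number_of_nodes()
    if n < 2:
        raise ValueError("cluster score needs >= 2 nodes")
    return _density(n, sub.number_of_edges()) * n


def vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """weight(v) = k_max * density of the highest k-core of v's closed
    neighborhood; isolated vertices get 0."""
    weights: dict[str, float] = {}
    for v in graph.nodes:
        nbrs = set(graph.neighbors(v)) | {v}
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(nbrs)
        core_num = nx.core_number(sub)
        k_max = max(core_num.values())
        core_nodes = [u for u, k in core_num.items() if k >= k_max]
        core = sub.subgraph(core_nodes)
        weights[v] = k_max * _density(core.number_of_nodes(), core.number_of_edges())
    return weights


def find_clusters(graph: nx.Graph, params: McodeParams = McodeParams()) -> list[Cluster]:
    """Greedy complex growth from high-weight seeds.

    Each vertex joins at most one cluster; breadth-first expansion admits
    neighbors with weight >= seed_weight * (1 - vwp) up to ``max_depth``
    hops. Haircut prunes vertices with fewer than 2 links into the
    cluster; fluff adds boundary neighbors whose closed-neighborhood
    density exceeds the fluff threshold (fluffed nodes may repeat across
    clusters, as in the original heuristic). Clusters below
    ``min_cluster_size`` are discarded; ranking is by score desc, then
    size desc, then seed id.
    """
    w = vertex_weights(graph)
    assigned: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    # deterministic seed order: weight desc, then node id
    for seed in sorted(graph.nodes, key=lambda v: (-w[v], str(v))):
        if seed in assigned or w[seed] <= 0.0:
            continue
        cutoff = w[seed] * (1.0 - params.vertex_weight_percentage)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for nb in graph.neighbors(u):
                    if nb in members or nb in assigned:
                        continue
                    if w[nb] >= cutoff:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        if params.haircut:
            changed = True
            while changed:
                sub = graph.subgraph(members)
                weak = [u for u in members if sub.degree(u) < 2]
                changed = bool(weak)
                members -= set(weak)
        if not members:
            continue
        assigned |= members
        fluffed = set(members)
        if params.fluff:
            for u in sorted(members):
                for nb in graph.neighbors(u):
                    if nb in fluffed:
                        continue
                    closed = set(graph.neighbors(nb)) | {nb}
                    sub = graph.subgraph(closed)
                    if _density(sub.number_of_nodes(), sub.number_of_edges()) > params.fluff_density_threshold:
                        fluffed.add(nb)
        if len(fluffed) >= params.min_cluster_size:
            raw.append((seed, fluffed))
    clusters = [
        Cluster.from_subgraph(graph.subgraph(members), seed) for seed, members in raw
    ]
    clusters.sort(key=lambda c: (-c.score, -c.n_nodes, str(c.seed)))
    for i, c in enumerate(clusters):
        c.rank = i + 1
    return clusters


def cluster_report(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular cluster summary: network, score, nodes, edges."""
    return pd.DataFrame(
        [
            {"network": c.rank, "score": round(c.score, 2), "nodes": c.n_nodes, "edges": c.n_edges}
            for c in clusters
        ],
        columns=["network", "score", "nodes", "edges"],
    )
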