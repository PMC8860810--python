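"""Shortest-pathway analysis on a partial-correlation network.

An edge with weight w (a regularized partial correlation) is assigned the
distance 1/|w|: strong conditional associations — of either sign — make
short steps.  Shortest routes between maltreatment (CM) nodes and the
ED-specific symptom nodes are then found with Dijkstra's algorithm, and
all co-optimal routes per pair are reported so tie-breaking never hides a
pathway.  Setting ``unweighted=True`` instead counts hops, the literal
"minimum number of steps" reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datasets import CM_NODES, ED_SPECIFIC_NODES
from .estimation import EDGE_TOL, RegularizedNetwork


class PathwayError(ValueError):
    """Raised for invalid pathway queries."""


@dataclass
class DistanceGraph:
    """Undirected graph with distance 1/|w| per present edge.

    The graph keeps both the traversal distance (``dist``) and the signed
    partial correlation (``weight``) on each edge, so reported routes can
    state whether each step is a positive or negative association.
    """

    graph: nx.Graph
    node_names: list[str]
    source_network: str = ""

    @classmethod
    def from_network(
        cls, net: RegularizedNetwork, unweighted: bool = False
    ) -> "DistanceGraph":
        G = nx.Graph()
        G.add_nodes_from(net.node_names)
        for i, a in enumerate(net.node_names):
            for j in range(i + 1, net.p):
                w = net.W[i, j]
                if abs(w) > EDGE_TOL:
                    dist = 1.0 if unweighted else 1.0 / abs(w)
                    G.add_edge(a, net.node_names[j], dist=dist, weight=float(w))
        return cls(
            graph=G,
            node_names=list(net.node_names),
            source_network=net.group_label,
        )


def to_distance_graph(
    net: RegularizedNetwork, unweighted: bool = False
) -> DistanceGraph:
    """Transform edge weights to traversal distances D_ij = 1/|W_ij|."""
    return DistanceGraph.from_network(net, unweighted=unweighted)


def dijkstra(
    D: DistanceGraph, source: str
) -> tuple[dict[str, float], dict[str, list[str]]]:
    """Single-source shortest distances and predecessor *sets*.

    Returns ``(distances, predecessors)``; unreachable nodes get distance
    ``inf`` and an empty predecessor list.  Keeping every co-optimal
    predecessor makes all tied routes recoverable.
    """
    if source not in D.graph:
        raise PathwayError(
            f"unknown node {source!r}; valid nodes: {sorted(D.graph.nodes)}"
        )
    pred, dist = nx.dijkstra_predecessor_and_distance(D.graph, source, weight="dist")
    distances = {n: dist.get(n, float("inf")) for n in D.node_names}
    predecessors = {n: sorted(pred.get(n, [])) for n in D.node_names}
    return distances, predecessors


@dataclass
class PathResult:
    """All co-optimal shortest routes between one source/target pair."""

    source: str
    target: str
    reachable: bool
    distance: float  # inf when unreachable
    paths: list[list[str]] = field(default_factory=list)
    #: per path, the signed weight of each traversed edge
    edge_weights: list[list[float]] = field(default_factory=list)

    @property
    def hops(self) -> list[int]:
        return [len(p) - 1 for p in self.paths]

    def traverses(self, *nodes: str) -> bool:
        """True if every reported route visits all the given nodes."""
        return bool(self.paths) and all(
            all(n in path for n in nodes) for path in self.paths
        )

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "reachable": self.reachable,
            "distance": self.distance if self.reachable else None,
            "hops": self.hops,
            "paths": self.paths,
            "edge_weights": self.edge_weights,
        }


def shortest_pathways(
    net: RegularizedNetwork,
    sources: list[str] | None = None,
    targets: list[str] | None = None,
    unweighted: bool = False,
) -> tuple[list[PathResult], nx.Graph]:
    """Shortest routes from each maltreatment node to each symptom target.

    Defaults: sources are the five CTQ maltreatment nodes, targets the
    ED-specific symptoms (body dissatisfaction, bulimia).  Every
    co-optimal route per pair is returned, ordered by node-index
    sequence.  The second return value is the union subgraph of all
    reported routes (the continuous-line "shortest-pathway network");
    its edges carry the signed weight and a ``on_shortest_path`` flag.

    Unreachable pairs are reported with ``reachable=False``, not raised.
    """
    names = net.node_names
    sources = list(sources) if sources is not None else [n for n in CM_NODES if n in names]
    targets = list(targets) if targets is not None else [n for n in ED_SPECIFIC_NODES if n in names]
    if set(sources) & set(targets):
        raise PathwayError("sources and targets must be disjoint")
    for n in sources + targets:
        if n not in names:
            raise PathwayError(f"unknown node {n!r}; valid nodes: {sorted(names)}")
    D = to_distance_graph(net, unweighted=unweighted)
    G = D.graph
    index = {n: i for i, n in enumerate(names)}
    results: list[PathResult] = []
    union = nx.Graph()
    union.add_nodes_from(names)
    for s in sources:
        for t in targets:
            try:
                dist = nx.dijkstra_path_length(G, s, t, weight="dist")
            except nx.NetworkXNoPath:
                results.append(
                    PathResult(source=s, target=t, reachable=False, distance=float("inf"))
                )
                continue
            routes = sorted(
                nx.all_shortest_paths(G, s, t, weight="dist"),
                key=lambda p: [index[n] for n in p],
            )
            weights = [
                [G.edges[a, b]["weight"] for a, b in zip(p[:-1], p[1:])] for p in routes
            ]
            results.append(
                PathResult(
                    source=s,
                    target=t,
                    reachable=True,
                    distance=float(dist),
                    paths=[list(p) for p in routes],
                    edge_weights=weights,
                )
            )
            for p in routes:
                for a, b in zip(p[:-1], p[1:]):
                    union.add_edge(
                        a,
                        b,
                        weight=G.edges[a, b]["weight"],
                        dist=G.edges[a, b]["dist"],
                        on_shortest_path=True,
                    )
    return results, union


def pathway_report(results: list[PathResult]) -> dict:
    """JSON-ready summary keyed 'source->target'."""
    return {f"{r.source}->{r.target}": r.to_dict() for r in results}
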