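"""Shortest pathways: distance transform, Dijkstra, co-optimal routes."""

import numpy as np
import pytest

from symptomnet import (
    dijkstra,
    estimate_network,
    generate_dataset,
    paper_topology_spec,
    shortest_pathways,
    to_distance_graph,
)
from symptomnet.pathways import DistanceGraph, PathwayError

import networkx as nx

from conftest import network_from_weights
from oracles import enumerate_shortest_paths, random_distance_graph


def graph_from_adjacency(adj: dict[str, dict[str, float]]) -> DistanceGraph:
    G = nx.Graph()
    G.add_nodes_from(adj)
    for a, nbrs in adj.items():
        for b, d in nbrs.items():
            G.add_edge(a, b, dist=d, weight=1.0 / d)
    return DistanceGraph(graph=G, node_names=sorted(adj))


class TestDistanceTransform:
    def test_reciprocal_absolute_weight(self):
        net = network_from_weights(["a", "b", "c"], {("a", "b"): 0.25, ("b", "c"): -0.5})
        D = to_distance_graph(net)
        assert D.graph.edges["a", "b"]["dist"] == pytest.approx(4.0)
        assert D.graph.edges["b", "c"]["dist"] == pytest.approx(2.0)
        assert D.graph.edges["b", "c"]["weight"] == pytest.approx(-0.5)
        assert not D.graph.has_edge("a", "c")

    def test_stronger_edge_is_strictly_shorter(self):
        net = network_from_weights(["a", "b", "c"], {("a", "b"): 0.2, ("b", "c"): 0.4})
        D = to_distance_graph(net)
        assert D.graph.edges["b", "c"]["dist"] < D.graph.edges["a", "b"]["dist"]

    def test_unweighted_counts_hops(self):
        net = network_from_weights(["a", "b"], {("a", "b"): 0.25})
        D = to_distance_graph(net, unweighted=True)
        assert D.graph.edges["a", "b"]["dist"] == 1.0


class TestDijkstra:
    def test_triangle_goes_the_long_way_round(self):
        D = graph_from_adjacency(
            {"A": {"B": 1.0, "C": 3.0}, "B": {"A": 1.0, "C": 1.0}, "C": {"A": 3.0, "B": 1.0}}
        )
        dist, pred = dijkstra(D, "A")
        assert dist["C"] == pytest.approx(2.0)
        assert pred["C"] == ["B"]

    def test_unreachable_node_reports_infinity(self):
        D = graph_from_adjacency({"A": {"B": 5.0}, "B": {"A": 5.0}, "C": {}})
        dist, pred = dijkstra(D, "A")
        assert dist["C"] == float("inf")
        assert pred["C"] == []

    def test_square_keeps_both_co_optimal_predecessors(self):
        D = graph_from_adjacency(
            {
                "A": {"B": 1.0, "C": 1.0},
                "B": {"A": 1.0, "D": 1.0},
                "C": {"A": 1.0, "D": 1.0},
                "D": {"B": 1.0, "C": 1.0},
            }
        )
        dist, pred = dijkstra(D, "A")
        assert dist["D"] == pytest.approx(2.0)
        assert pred["D"] == ["B", "C"]

    def test_unknown_source_rejected(self):
        D = graph_from_adjacency({"A": {"B": 1.0}, "B": {"A": 1.0}})
        with pytest.raises(PathwayError, match="valid nodes"):
            dijkstra(D, "Z")

    @pytest.mark.parametrize("discrete", [False, True])
    def test_matches_exhaustive_enumeration(self, discrete):
        rng = np.random.default_rng(5 if discrete else 6)
        for _ in range(30):
            adj = random_distance_graph(rng, discrete=discrete)
            D = graph_from_adjacency(adj)
            src = sorted(adj)[0]
            dist, _ = dijkstra(D, src)
            for target in sorted(adj):
                if target == src:
                    continue
                best, _ = enumerate_shortest_paths(adj, src, target)
                assert dist[target] == pytest.approx(best, abs=1e-9)


class TestShortestPathways:
    def test_all_co_optimal_routes_reported_in_order(self):
        net = network_from_weights(
            ["s", "x", "y", "t"],
            {("s", "x"): 0.5, ("x", "t"): 0.5, ("s", "y"): 0.5, ("y", "t"): 0.5},
        )
        results, union = shortest_pathways(net, sources=["s"], targets=["t"])
        (r,) = results
        assert r.paths == [["s", "x", "t"], ["s", "y", "t"]]
        assert r.distance == pytest.approx(4.0)
        assert r.hops == [2, 2]
        assert set(union.edges) == {("s", "x"), ("x", "t"), ("s", "y"), ("y", "t")}

    def test_total_distance_is_sum_of_reciprocal_weights(self):
        net = network_from_weights(["s", "m", "t"], {("s", "m"): 0.25, ("m", "t"): -0.5})
        results, _ = shortest_pathways(net, sources=["s"], targets=["t"])
        (r,) = results
        assert r.distance == pytest.approx(4.0 + 2.0)
        assert r.edge_weights == [[0.25, -0.5]]

    def test_empty_network_is_unreachable_not_an_error(self):
        net = network_from_weights(["s", "t"], {})
        results, union = shortest_pathways(net, sources=["s"], targets=["t"])
        assert not results[0].reachable
        assert results[0].distance == float("inf")
        assert union.number_of_edges() == 0

    def test_overlapping_sources_and_targets_rejected(self):
        net = network_from_weights(["s", "t"], {("s", "t"): 0.3})
        with pytest.raises(PathwayError, match="disjoint"):
            shortest_pathways(net, sources=["s"], targets=["s", "t"])

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(17)
        names = ["a", "b", "c", "d", "e"]
        edges = {("a", "b"): 0.4, ("b", "c"): 0.3, ("c", "d"): 0.5, ("a", "e"): 0.2, ("e", "d"): 0.45}
        net = network_from_weights(names, edges)
        perm = list(rng.permutation(names))
        net_perm = network_from_weights(perm, edges)
        r1, _ = shortest_pathways(net, sources=["a"], targets=["d"])
        r2, _ = shortest_pathways(net_perm, sources=["a"], targets=["d"])
        assert r1[0].distance == pytest.approx(r2[0].distance)
        assert sorted(map(tuple, r1[0].paths)) == sorted(map(tuple, r2[0].paths))

    def test_planted_bn_routes_pass_through_abuse_and_ineffectiveness(self):
        data = generate_dataset(paper_topology_spec("BN", n_subjects=2000, seed=2))
        net = estimate_network(data)
        results, _ = shortest_pathways(net)
        by_pair = {(r.source, r.target): r for r in results}
        for cm in ("emotional_neglect", "sexual_abuse", "physical_neglect", "physical_abuse"):
            r = by_pair[(cm, "body_dissatisfaction")]
            assert r.reachable and r.traverses("emotional_abuse", "ineffectiveness")
            r = by_pair[(cm, "bulimia")]
            assert r.reachable and r.traverses(
                "emotional_abuse", "ineffectiveness", "interoceptive_awareness"
            )

    def test_planted_bed_route_to_bulimia_includes_impulsivity(self):
        data = generate_dataset(paper_topology_spec("BED", n_subjects=2000, seed=2))
        net = estimate_network(data)
        results, _ = shortest_pathways(net)
        by_pair = {(r.source, r.target): r for r in results}
        r = by_pair[("emotional_abuse", "bulimia")]
        assert r.reachable and r.traverses("impulsivity", "interoceptive_awareness")
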