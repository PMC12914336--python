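from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from comodnet.datatypes import GeneSet
from comodnet.drivers import (
    flow_centrality,
    module_pair_distance,
    node_distance_sum,
    screen_drivers,
    shortest_path_counts,
)
from comodnet.synthetic import SyntheticSpec, simulate_interactome

from oracles import brute_force_flow, random_connected_gnp


def gs(name, genes):
    return GeneSet.from_iterable(name, genes)


def path_graph(*nodes):
    g = nx.Graph()
    nx.add_path(g, nodes)
    return g


class TestShortestPathCounts:
    def test_single_path(self):
        g = path_graph("a", "v", "b")
        dist, sigma = shortest_path_counts(g, "a")
        assert dist["b"] == 2 and sigma["b"] == 1

    def test_four_cycle_two_paths(self):
        g = nx.Graph([("a", "x"), ("x", "b"), ("b", "y"), ("y", "a")])
        dist, sigma = shortest_path_counts(g, "a")
        assert dist["b"] == 2 and sigma["b"] == 2

    def test_missing_source_rejected(self):
        with pytest.raises(KeyError):
            shortest_path_counts(path_graph("a", "b"), "zz")

    def test_sigma_matches_enumeration_on_random_graph(self):
        rng = np.random.default_rng(17)
        g = random_connected_gnp(8, 0.5, rng)
        for s in g.nodes:
            dist, sigma = shortest_path_counts(g, s)
            for t in g.nodes:
                if t == s:
                    continue
                paths = list(nx.all_shortest_paths(g, s, t))
                assert dist[t] == len(paths[0]) - 1
                assert sigma[t] == len(paths)


class TestModulePairDistance:
    def test_three_node_path_mean(self):
        g = path_graph("a1", "a2", "b1")
        res = module_pair_distance(g, gs("A", ["a1", "a2"]), gs("B", ["b1"]))
        assert res.d_shortest == pytest.approx(1.5)
        assert res.reachable_pair_fraction == 1.0

    def test_identical_singletons_zero(self):
        g = path_graph("a", "b")
        res = module_pair_distance(g, gs("A", ["a"]), gs("B", ["a"]))
        assert res.d_shortest == 0.0

    def test_unreachable_pairs_excluded_from_mean(self):
        g = path_graph("a1", "a2", "b1")
        g.add_node("b2")  # disconnected
        res = module_pair_distance(g, gs("A", ["a1", "a2"]), gs("B", ["b1", "b2"]))
        assert res.d_shortest == pytest.approx(1.5)
        assert res.reachable_pair_fraction == pytest.approx(0.5)

    def test_fully_unreachable_rejected(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        with pytest.raises(ValueError, match="reachable"):
            module_pair_distance(g, gs("A", ["a"]), gs("B", ["b"]))


class TestFlowCentrality:
    def test_mandatory_interior_node_scores_one(self):
        table = flow_centrality(path_graph("a", "v", "b"), gs("A", ["a"]), gs("B", ["b"]))
        scores = table.scores.set_index("node")
        assert scores.loc["v", "fc_normalized"] == pytest.approx(1.0)
        assert scores.loc["a", "fc_normalized"] == 0.0  # endpoint convention

    def test_diamond_splits_evenly(self):
        g = nx.Graph([("a", "v1"), ("v1", "b"), ("a", "v2"), ("v2", "b")])
        scores = flow_centrality(g, gs("A", ["a"]), gs("B", ["b"])).scores.set_index("node")
        assert scores.loc["v1", "fc_normalized"] == pytest.approx(0.5)
        assert scores.loc["v2", "fc_normalized"] == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_splits(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            g = random_connected_gnp(8, 0.5, rng)
            nodes = list(g.nodes)
            for a, b in [((0, 1), (2, 3)), ((4, 5), (6, 7))]:
                A = [nodes[i] for i in a]
                B = [nodes[i] for i in b]
                table = flow_centrality(g, gs("A", A), gs("B", B))
                fc_ref, raw_ref, _, _ = brute_force_flow(g, A, B)
                got = table.scores.set_index("node")
                for v in g.nodes:
                    assert got.loc[v, "fc_normalized"] == pytest.approx(fc_ref[v], abs=1e-12)
                    assert got.loc[v, "fc_raw"] == raw_ref[v]

    def test_interior_mass_identity(self):
        """For each reachable pair the interior fractions sum to
        d(a,b) - 1, so total normalized flow equals mean(d - 1)."""
        rng = np.random.default_rng(5)
        g = random_connected_gnp(8, 0.4, rng)
        nodes = sorted(g.nodes)
        A, B = nodes[:3], nodes[3:6]
        table = flow_centrality(g, gs("A", A), gs("B", B))
        dist_sum = 0.0
        n_pairs = 0
        seen = set()
        for a in A:
            for b in B:
                if a == b or frozenset((a, b)) in seen:
                    continue
                seen.add(frozenset((a, b)))
                dist_sum += nx.shortest_path_length(g, a, b) - 1
                n_pairs += 1
        total = table.scores["fc_normalized"].sum()
        assert total * len(A) * len(B) == pytest.approx(dist_sum, abs=1e-9)

    def test_parallel_path_dilutes_original_interior(self):
        g1 = path_graph("a", "v", "b")
        g2 = g1.copy()
        nx.add_path(g2, ["a", "w", "b"])
        fc1 = flow_centrality(g1, gs("A", ["a"]), gs("B", ["b"])).scores.set_index("node")
        fc2 = flow_centrality(g2, gs("A", ["a"]), gs("B", ["b"])).scores.set_index("node")
        assert fc2.loc["v", "fc_normalized"] < fc1.loc["v", "fc_normalized"]

    def test_absent_module_genes_dropped_with_warning(self, caplog):
        g = path_graph("a", "v", "b")
        with caplog.at_level("WARNING"):
            table = flow_centrality(g, gs("A", ["a", "ghost"]), gs("B", ["b"]))
        assert table.module_a == ("a",)


class TestNodeDistanceSum:
    def test_simple_path(self):
        sums, reach = node_distance_sum(path_graph("a", "v", "b"), gs("A", ["a"]), gs("B", ["b"]))
        assert sums["v"] == 2 and reach["v"] == 2

    def test_isolated_node_flagged_by_zero_reach(self):
        g = path_graph("a", "v", "b")
        g.add_node("w")
        sums, reach = node_distance_sum(g, gs("A", ["a"]), gs("B", ["b"]))
        assert sums["w"] == 0 and reach["w"] == 0

    def test_star_center_distance(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        sums, _ = node_distance_sum(g, gs("A", [1, 2]), gs("B", [3, 4]))
        assert sums[0] == 4  # all members at distance 1


class TestScreenDrivers:
    def make_tables(self, graphs, modules):
        tables = {}
        for (name, g), (a, b) in zip(graphs.items(), modules):
            tables[name] = flow_centrality(g, a, b, pair_name=name)
        return tables

    def test_gene_in_all_pairs_is_driver(self):
        g = path_graph("a", "v", "b")
        tables = {
            (f"d{i}", f"d{j}"): flow_centrality(g, gs("A", ["a"]), gs("B", ["b"]),
                                                pair_name=(f"d{i}", f"d{j}"))
            for i, j in combinations(range(3), 2)
        }
        call = screen_drivers(tables, k=1)
        assert "v" in call.drivers.genes

    def test_gene_in_two_pairs_only_is_not_driver(self):
        g1 = path_graph("a", "v", "b")
        g2 = path_graph("a", "w", "b")
        t = {}
        for pair, g in [(("d1", "d2"), g1), (("d1", "d3"), g1), (("d2", "d3"), g2)]:
            t[pair] = flow_centrality(g, gs("A", ["a"]), gs("B", ["b"]), pair_name=pair)
        call = screen_drivers(t, k=1)
        assert "v" not in call.drivers.genes

    def test_planted_bridges_recovered_exactly(self):
        spec = SyntheticSpec(seed=17)
        mods = [gs(f"M{i}", [f"M{i}_{j}" for j in range(10)]) for i in range(3)]
        graph, truth = simulate_interactome(spec, mods)
        tables = {}
        for i, j in combinations(range(3), 2):
            pair = (f"M{i}", f"M{j}")
            tables[pair] = flow_centrality(graph, mods[i], mods[j], pair_name=pair)
        call = screen_drivers(tables, k=10)
        assert set(call.drivers.genes) == set(truth.bridge_nodes)

    def test_intersection_subset_of_each_qualifying_list(self):
        spec = SyntheticSpec(seed=2)
        mods = [gs(f"M{i}", [f"M{i}_{j}" for j in range(8)]) for i in range(3)]
        graph, _ = simulate_interactome(spec, mods)
        tables = {}
        for i, j in combinations(range(3), 2):
            pair = (f"M{i}", f"M{j}")
            tables[pair] = flow_centrality(graph, mods[i], mods[j], pair_name=pair)
        call = screen_drivers(tables, k=5)
        for q in call.qualifying.values():
            assert set(call.drivers.genes) <= q
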