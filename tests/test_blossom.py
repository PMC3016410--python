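import math
from itertools import permutations

import networkx as nx
import numpy as np
import pytest

from petals import blossom as bl
from petals import go_rules
from petals.coexpression import CoexpressionMap

from conftest import make_network


def brute_force_paths(graph, a, b, max_len):
    """Independent oracle: filter node permutations for adjacency."""
    if a == b:
        return {(a,)}
    found = set()
    nodes = list(graph.nodes)
    others = [n for n in nodes if n not in (a, b)]
    for k in range(0, min(max_len - 1, len(others)) + 1):
        for middle in permutations(others, k):
            path = (a, *middle, b)
            if all(graph.has_edge(u, v) for u, v in zip(path, path[1:])):
                found.add(path)
    return found


class TestShortestPathDistance:
    def test_same_node(self, triangle):
        assert bl.shortest_path_distance(triangle, "a", "a") == 0

    def test_disconnected(self, triangle):
        triangle.add_node("island")
        assert bl.shortest_path_distance(triangle, "a", "island") == math.inf

    def test_path_graph(self):
        graph = make_network([("a", "x"), ("x", "y"), ("y", "b")])
        assert bl.shortest_path_distance(graph, "a", "b") == 3

    def test_absent_node(self, triangle):
        with pytest.raises(KeyError):
            bl.shortest_path_distance(triangle, "a", "zzz")


class TestDiameterBound:
    def test_raw_distance_wins_even_if_imputed_shorter(self):
        raw = make_network([("a", "x"), ("x", "y"), ("y", "b")])
        imputed = raw.copy()
        imputed.add_edge("a", "b")
        assert bl.diameter_bound(raw, imputed, "a", "b") == 3

    def test_imputed_fallback_on_disconnection(self):
        raw = make_network([("a", "x")])
        raw.add_node("b")
        imputed = raw.copy()
        imputed.add_edge("x", "b")
        assert bl.diameter_bound(raw, imputed, "a", "b") == 2

    def test_disconnected_in_both(self):
        raw = make_network([("a", "x")])
        raw.add_node("b")
        assert bl.diameter_bound(raw, raw, "a", "b") == math.inf


class TestAllPathsDfs:
    def test_path_graph(self):
        graph = make_network([("a", "b"), ("b", "c")])
        assert bl.all_paths_dfs(graph, "a", "c", 2) == {("a", "b", "c")}

    def test_four_cycle(self):
        graph = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert bl.all_paths_dfs(graph, "a", "c", 2) == {("a", "b", "c"), ("a", "d", "c")}

    def test_k4_five_paths(self):
        graph = nx.complete_graph(["a", "b", "c", "d"])
        paths = bl.all_paths_dfs(graph, "a", "d", 3)
        assert len(paths) == 5
        assert paths == brute_force_paths(graph, "a", "d", 3)

    def test_infinite_bound_rejected(self, triangle):
        with pytest.raises(ValueError, match="finite"):
            bl.all_paths_dfs(triangle, "a", "b", math.inf)

    def test_inclusive_bound_contains_shortest_path(self):
        graph = make_network([("a", "x"), ("x", "b"), ("a", "y"), ("y", "z"), ("z", "b")])
        d = bl.shortest_path_distance(graph, "a", "b")
        assert any(len(p) - 1 == d for p in bl.all_paths_dfs(graph, "a", "b", d))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        graph = nx.gnp_random_graph(n, 0.4, seed=seed)
        graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in range(n)})
        nodes = sorted(graph.nodes)
        for a in nodes:
            for b in nodes:
                if a >= b:
                    continue
                for bound in range(1, n):
                    assert bl.all_paths_dfs(graph, a, b, bound) == brute_force_paths(
                        graph, a, b, bound
                    )


def toy_scoring(r_values):
    """CoexpressionMap + annotations + rules over a small node universe."""
    genes = sorted(r_values_nodes(r_values))
    n = len(genes)
    matrix = np.zeros((n, n))
    np.fill_diagonal(matrix, 1.0)
    cm = CoexpressionMap(genes=genes, matrix=matrix)
    for (u, v), r in r_values.items():
        i, j = genes.index(u), genes.index(v)
        matrix[i, j] = matrix[j, i] = r
    return cm


def r_values_nodes(r_values):
    return {g for pair in r_values for g in pair}


class TestBuildPetal:
    def _setup(self, r_ab=0.8, r_bc=-0.7):
        network = make_network([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        cm = toy_scoring({("a", "b"): r_ab, ("b", "c"): r_bc,
                          ("c", "d"): 0.0, ("d", "a"): 0.0})
        leaf = {"a": {"sig"}, "b": {"sig"}, "c": {"sig"}}
        rules = [go_rules.AssociationRule(terms=frozenset({"sig"}), support=3)]
        return network, cm, rules, leaf

    def test_mean_of_absolutes(self):
        network, cm, rules, leaf = self._setup()
        assert bl.mean_abs_coexpression(("a", "b", "c"), cm) == pytest.approx(0.75)

    def test_path_kept_when_above_gamma_and_significant(self):
        network, cm, rules, leaf = self._setup()
        petal = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                               gamma=0.6, p_threshold=0.5, seed=0, n_null=200)
        assert not petal.is_empty
        assert petal.paths[0].mean_abs_coexpr == pytest.approx(0.75)

    def test_low_coexpression_empty_petal(self):
        network, cm, rules, leaf = self._setup(r_ab=0.3, r_bc=0.2)
        petal = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                               gamma=0.6, p_threshold=0.5, seed=0, n_null=200)
        assert petal.is_empty
        assert petal.paths == []

    def test_merged_paths_share_nodes_once(self):
        _, _, rules, _ = self._setup()
        # 4-cycle plus a rule-free background chain so null paths can miss
        network = make_network(
            [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"),
             ("x1", "x2"), ("x2", "x3"), ("x3", "x4"), ("x4", "x5"), ("x5", "x1")]
        )
        cm2 = toy_scoring({("a", "b"): 0.9, ("b", "c"): 0.9,
                           ("c", "d"): 0.9, ("d", "a"): 0.9})
        leaf = {g: {"sig"} for g in "abcd"}
        petal = bl.build_petal("c", [("a", "b", "c"), ("a", "d", "c")], cm2, rules,
                               leaf, network, gamma=0.6, p_threshold=0.9, seed=0, n_null=100)
        assert len(petal.paths) == 2
        assert petal.n_nodes == 4

    def test_petal_edges_covered_by_paths(self):
        network, cm, rules, leaf = self._setup()
        petal = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                               gamma=0.6, p_threshold=0.5, seed=0, n_null=100)
        path_edges = {
            frozenset((u, v)) for s in petal.paths for u, v in zip(s.path, s.path[1:])
        }
        assert {frozenset(e) for e in petal.graph.edges} == path_edges

    def test_monotone_in_gamma_and_p(self):
        network, cm, rules, leaf = self._setup()
        loose = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                               gamma=0.6, p_threshold=0.5, seed=1, n_null=200)
        tight_gamma = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                                     gamma=0.9, p_threshold=0.5, seed=1, n_null=200)
        tight_p = bl.build_petal("c", [("a", "b", "c")], cm, rules, leaf, network,
                                 gamma=0.6, p_threshold=0.001, seed=1, n_null=200)
        for tight in (tight_gamma, tight_p):
            assert set(tight.graph.nodes) <= set(loose.graph.nodes)
            assert set(map(frozenset, tight.graph.edges)) <= set(map(frozenset, loose.graph.edges))

    def test_invalid_thresholds(self):
        network, cm, rules, leaf = self._setup()
        with pytest.raises(ValueError, match="gamma"):
            bl.build_petal("c", [], cm, rules, leaf, network, gamma=1.5)
        with pytest.raises(ValueError, match="p_threshold"):
            bl.build_petal("c", [], cm, rules, leaf, network, p_threshold=0.0)


class TestBuildBlossom:
    def test_driver_missing(self, default_bundle):
        with pytest.raises(KeyError, match="driver"):
            bl.build_blossom("nope", [], default_bundle.network, default_bundle.network,
                             None, [], {})

    def test_disconnected_candidate_absent(self):
        network = make_network([("drv", "m"), ("m", "c1")])
        network.add_node("c2")  # isolated
        cm = toy_scoring({("drv", "m"): 0.9, ("m", "c1"): 0.9})
        cm.genes.append("c2")
        leaf = {g: {"sig"} for g in ["drv", "m", "c1"]}
        rules = [go_rules.AssociationRule(terms=frozenset({"sig"}), support=2)]
        result = bl.build_blossom("drv", ["c1", "c2"], network, network, cm, rules, leaf,
                                  gamma=0.6, p_threshold=0.9, n_null=100)
        assert "c2" not in result.petals

    def test_candidate_via_imputed_edge_only(self):
        # rule-free x-chain gives the significance null paths to sample
        raw = make_network([("drv", "m"), ("x1", "x2"), ("x2", "x3"),
                            ("x3", "x4"), ("x4", "x1")])
        raw.add_node("c1")
        imputed = raw.copy()
        imputed.add_edge("m", "c1", observation_count=0, provenance="imputed")
        cm = toy_scoring({("drv", "m"): 0.9, ("m", "c1"): 0.9})
        leaf = {g: {"sig"} for g in ["drv", "m", "c1"]}
        rules = [go_rules.AssociationRule(terms=frozenset({"sig"}), support=2)]
        result = bl.build_blossom("drv", ["c1"], raw, imputed, cm, rules, leaf,
                                  gamma=0.6, p_threshold=0.9, n_null=100)
        assert "c1" in result.petals
        petal = result.petals["c1"]
        assert petal.graph["m"]["c1"]["provenance"] == "imputed"

    def test_deterministic_and_order_independent(self, default_bundle):
        from petals.coexpression import pearson_map
        from petals.go_rules import leaf_annotations, mine_rules

        b = default_bundle
        cm = pearson_map(b.expression)
        leaf = leaf_annotations(b.annotations, b.go_graph)
        rules = mine_rules(b.pathways, leaf, b.network, min_support=2)
        kwargs = dict(gamma=0.6, p_threshold=0.05, seed=42, n_null=300)
        one = bl.build_blossom(b.driver, b.candidates, b.network, b.network,
                               cm, rules, leaf, **kwargs)
        two = bl.build_blossom(b.driver, list(reversed(b.candidates)), b.network,
                               b.network, cm, rules, leaf, **kwargs)
        assert sorted(one.petals) == sorted(two.petals)
        for cand in one.petals:
            assert [s.p_value for s in one.petals[cand].paths] == [
                s.p_value for s in two.petals[cand].paths
            ]
            assert nx.utils.graphs_equal(one.petals[cand].graph, two.petals[cand].graph)

    def test_every_petal_contains_driver(self, default_bundle):
        from petals.coexpression import pearson_map
        from petals.go_rules import leaf_annotations, mine_rules

        b = default_bundle
        cm = pearson_map(b.expression)
        leaf = leaf_annotations(b.annotations, b.go_graph)
        rules = mine_rules(b.pathways, leaf, b.network, min_support=2)
        result = bl.build_blossom(b.driver, b.candidates, b.network, b.network,
                                  cm, rules, leaf, seed=0, n_null=300)
        assert result.petals
        for cand, petal in result.petals.items():
            assert b.driver in petal.graph
            assert cand in petal.graph
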