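"""Greedy dense-module search: score formula, growth rule, merging."""

import math

import networkx as nx
import numpy as np
import pytest

from tissuenet import grow_module, merge_modules, module_score, search_all


def reference_greedy(net: nx.Graph, seed: str, rate: float = 0.0) -> list[str]:
    """Independent re-implementation: rescan all candidates each step.

    Plain dict/loop arithmetic, no shared code with the search module.
    """
    members = [seed]
    total = net.nodes[seed].get("g", 0.0)
    zm = total / math.sqrt(1)
    while True:
        cands = sorted({n for m in members for n in net.neighbors(m)} - set(members))
        best_gene, best_zm, best_g = None, None, None
        for c in cands:
            g = net.nodes[c].get("g", 0.0)
            cand_zm = (total + g) / math.sqrt(len(members) + 1)
            if best_zm is None or cand_zm > best_zm or (cand_zm == best_zm and g > best_g):
                best_gene, best_zm, best_g = c, cand_zm, g
        if best_gene is None or best_zm <= zm * (1 + rate):
            return members
        members.append(best_gene)
        total += best_g
        zm = best_zm


class TestModuleScore:
    def test_single_gene_identity(self):
        assert module_score([3.0]) == pytest.approx(3.0)

    def test_three_equal_scores(self):
        assert module_score([2.0, 2.0, 2.0]) == pytest.approx(6 / math.sqrt(3))

    def test_zero_score_gene_dilutes(self):
        assert module_score([5.0, 0.0]) == pytest.approx(5 / math.sqrt(2))
        assert module_score([5.0, 0.0]) < 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            module_score([])


class TestGrowModule:
    def _star(self, scores: dict) -> nx.Graph:
        g = nx.Graph()
        nodes = list(scores)
        for n in nodes:
            g.add_node(n, g=scores[n])
        for n in nodes[1:]:
            g.add_edge(nodes[0], n)
        return g

    def test_worthless_neighbor_rejected(self):
        net = self._star({"S": 5.0, "N": 0.0})
        m = grow_module(net, "S")
        assert m.genes == ["S"] and m.Zm == pytest.approx(5.0)

    def test_strong_neighbor_accepted(self):
        net = self._star({"S": 2.0, "N": 4.0})
        m = grow_module(net, "S")
        assert m.genes == ["S", "N"]
        assert m.Zm == pytest.approx(6 / math.sqrt(2))

    def test_score_trajectory_strictly_increases(self, scored_random_network):
        net = scored_random_network(seed=7)
        m = grow_module(net, "N000")
        assert all(b > a for a, b in zip(m.trajectory, m.trajectory[1:]))
        assert m.Zm >= net.nodes["N000"]["g"]
        assert m.Zm == pytest.approx(
            module_score([net.nodes[n]["g"] for n in m.genes]), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_reference_greedy(self, scored_random_network, seed):
        net = scored_random_network(seed=seed, n=30)
        for start in list(net.nodes)[:5]:
            mine = grow_module(net, start)
            assert mine.genes == reference_greedy(net, start)

    def test_improvement_rate_shrinks_modules(self, scored_random_network):
        net = scored_random_network(seed=3)
        loose = grow_module(net, "N000", improvement_rate=0.0)
        strict = grow_module(net, "N000", improvement_rate=0.5)
        assert len(strict.genes) <= len(loose.genes)
        assert strict.genes == reference_greedy(net, "N000", rate=0.5)

    def test_invariant_to_edge_insertion_order(self):
        rng = np.random.default_rng(0)
        nodes = [f"N{i}" for i in range(15)]
        scores = {n: float(abs(rng.normal())) for n in nodes}
        edges = [(nodes[i], nodes[j]) for i in range(15) for j in range(i + 1, 15)
                 if rng.uniform() < 0.3]
        g1, g2 = nx.Graph(), nx.Graph()
        g1.add_nodes_from(nodes)
        g2.add_nodes_from(nodes)
        g1.add_edges_from(edges)
        g2.add_edges_from(edges[::-1])
        for g in (g1, g2):
            for n in nodes:
                g.nodes[n]["g"] = scores[n]
        for start in nodes:
            if g1.degree(start) == 0:
                continue
            assert grow_module(g1, start).genes == grow_module(g2, start).genes

    def test_second_order_neighborhood_reaches_across_gaps(self):
        # seed - bridge(g=0) - prize(g=10): order 1 stalls, order 2 jumps
        net = nx.Graph([("S", "B"), ("B", "P")])
        net.nodes["S"]["g"] = 3.0
        net.nodes["B"]["g"] = 0.0
        net.nodes["P"]["g"] = 10.0
        assert grow_module(net, "S", neighbor_order=1).genes == ["S"]
        m2 = grow_module(net, "S", neighbor_order=2)
        assert "P" in m2.genes

    def test_missing_seed_raises(self):
        with pytest.raises(KeyError):
            grow_module(nx.Graph([("A", "B")]), "Z")


class TestSearchAllAndMerge:
    def test_no_usable_seed_warns_and_returns_empty(self, scored_random_network):
        net = scored_random_network(seed=1)
        with pytest.warns(UserWarning, match="no seed"):
            assert search_all(net, ["ABSENT"]) == []

    def test_duplicate_seeds_give_identical_modules(self, scored_random_network):
        net = scored_random_network(seed=2)
        mods = search_all(net, ["N001", "N001"])
        assert len(mods) == 2
        assert mods[0].genes == mods[1].genes

    def test_merged_nodes_are_union_of_module_genes(self, scored_random_network):
        net = scored_random_network(seed=4)
        mods = search_all(net, ["N000", "N005", "N011"])
        merged = merge_modules(mods, net)
        assert set(merged.nodes) == set().union(*(m.genes for m in mods))
        # every merged edge exists in the tissue network
        assert all(net.has_edge(a, b) for a, b in merged.edges)

    def test_two_disjoint_modules_give_two_components(self):
        net = nx.Graph([("A", "B"), ("C", "D")])
        for n, s in zip("ABCD", [5.0, 4.0, 5.0, 4.0]):
            net.nodes[n]["g"] = s
        mods = search_all(net, ["A", "C"])
        merged = merge_modules(mods, net)
        assert nx.number_connected_components(merged) == 2

    def test_single_module_merge_is_induced_subgraph(self, scored_random_network):
        net = scored_random_network(seed=5)
        mods = search_all(net, ["N003"])
        merged = merge_modules(mods, net)
        induced = net.subgraph(mods[0].genes)
        assert set(merged.edges) == set(induced.edges)

    def test_provenance_records_contributing_seeds(self):
        net = nx.Graph([("A", "B"), ("B", "C")])
        for n, s in zip("ABC", [5.0, 6.0, 5.0]):
            net.nodes[n]["g"] = s
        merged = merge_modules(search_all(net, ["A", "C"]), net)
        assert merged.nodes["B"]["seeds"] == "A,C"

    def test_merge_requires_modules(self):
        with pytest.raises(ValueError):
            merge_modules([], nx.Graph())
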