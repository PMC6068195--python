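"""Key-driver KS scan and weighted centroid ranking."""

import networkx as nx
import numpy as np
import pytest

from tissuenet import (
    key_driver_scan,
    ks_keydriver_test,
    rank_centroids,
    weighted_centroid,
)


def _ba_network(seed: int, n: int = 100) -> nx.Graph:
    g = nx.barabasi_albert_graph(n, 2, seed=seed)
    g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in range(n)})
    rng = np.random.default_rng(seed)
    for node in g.nodes:
        g.nodes[node]["g"] = float(np.abs(rng.normal()))
    return g


class TestWeightedCentroid:
    def test_worked_example(self):
        net = nx.Graph()
        net.add_node("I", g=1.0)
        net.add_node("A", g=2.0)
        net.add_node("B", g=3.0)
        net.add_edge("I", "A", weight=0.5)
        net.add_edge("I", "B", weight=-0.4)
        assert weighted_centroid(net, "I") == pytest.approx(3.2)

    def test_isolated_gene_is_own_score(self):
        net = nx.Graph()
        net.add_node("X", g=2.5)
        assert weighted_centroid(net, "X") == 2.5

    def test_matches_bruteforce_from_adjacency(self):
        net = _ba_network(seed=0, n=20)
        rng = np.random.default_rng(1)
        for a, b in net.edges:
            net.edges[a, b]["weight"] = float(rng.uniform(-1, 1))
        for gene in net.nodes:
            expected = net.nodes[gene]["g"]
            for a, b, d in net.edges(data=True):
                if gene == a:
                    expected += abs(d["weight"]) * net.nodes[b]["g"]
                elif gene == b:
                    expected += abs(d["weight"]) * net.nodes[a]["g"]
            assert weighted_centroid(net, gene) == pytest.approx(expected)

    def test_positive_neighbor_never_decreases_centroid(self):
        net = nx.Graph()
        net.add_node("I", g=1.0)
        net.add_node("A", g=2.0)
        net.add_edge("I", "A", weight=0.5)
        before = weighted_centroid(net, "I")
        net.add_node("B", g=4.0)
        net.add_edge("I", "B", weight=0.3)
        assert weighted_centroid(net, "I") >= before

    def test_absent_gene_raises(self):
        with pytest.raises(KeyError):
            weighted_centroid(nx.Graph(), "Z")


class TestRankCentroids:
    def test_ties_break_lexicographically(self):
        net = nx.Graph()
        for n in ["B", "A", "C"]:
            net.add_node(n, g=1.5)
        table = rank_centroids(net)
        assert table["gene_id"].tolist() == ["A", "B", "C"]
        assert table["rank"].tolist() == [1, 2, 3]

    def test_single_node(self):
        net = nx.Graph()
        net.add_node("X", g=1.0)
        assert len(rank_centroids(net)) == 1

    def test_planted_hub_ranks_top(self, small_planted_study):
        from tissuenet import attach_scores, ar1_ld_source, clean_interactions, \
            coexpression_filter, run_gene_assoc

        study = small_planted_study
        assoc = run_gene_assoc(study.variants, study.genes,
                               ar1_ld_source(study.config.ld_rho))
        net = attach_scores(
            coexpression_filter(clean_interactions(study.edges), study.expression),
            assoc,
        )
        table = rank_centroids(net)
        hub_rank = int(table.loc[table["gene_id"] == study.truth.hub_gene, "rank"].iloc[0])
        assert hub_rank <= max(1, int(0.05 * len(table)))


class TestKSKeyDriver:
    def test_low_degree_untestable(self):
        net = nx.Graph([("A", "B")])
        for n in "AB":
            net.nodes[n]["g"] = 1.0
        assert ks_keydriver_test(net, "A") is None

    def test_extreme_neighbors_give_minimal_p(self):
        net = _ba_network(seed=2, n=50)
        hub = "HUB"
        net.add_node(hub, g=0.1)
        top = sorted(net.nodes, key=lambda n: -net.nodes[n]["g"])[:8]
        for t in top:
            if t != hub:
                net.add_edge(hub, t)
        background_max = max(net.nodes[n]["g"] for n in net.nodes if n != hub)
        for t in net.neighbors(hub):
            net.nodes[t]["g"] = background_max + 1.0
        p = ks_keydriver_test(net, hub)
        # all neighbor scores exceed the entire background: minimal attainable p
        worse = ks_keydriver_test(net, sorted(net.neighbors(hub))[0])
        assert p < 0.01 and p <= worse

    def test_type_one_error_calibrated(self):
        """Neighbors drawn from the background null reject at ~nominal rate."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            neighbors = rng.normal(size=10)
            background = rng.normal(size=99)
            if ks_2samp(neighbors, background, alternative="less").pvalue < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_null_network_has_no_key_drivers(self):
        counts = [int(key_driver_scan(_ba_network(seed=s))["is_key_driver"].sum())
                  for s in range(20)]
        assert sum(c <= 1 for c in counts) >= 19

    def test_planted_hub_detected(self):
        detected = 0
        for s in range(10):
            net = _ba_network(seed=100 + s)
            top10 = sorted(net.nodes, key=lambda n: -net.nodes[n]["g"])[:10]
            net.add_node("HUB", g=0.5)
            for t in top10:
                net.add_edge("HUB", t, weight=1.0)
            table = key_driver_scan(net).set_index("gene_id")
            detected += bool(table.loc["HUB", "is_key_driver"])
        assert detected >= 9

    def test_scan_table_shape_and_threshold(self):
        net = _ba_network(seed=7, n=40)
        table = key_driver_scan(net, alpha=0.05)
        assert len(table) == 40
        assert set(table.columns) >= {"gene_id", "degree", "n_sig_neighbors",
                                      "ks_p", "is_key_driver", "centroid"}
        tested = table[table["testable"]]
        assert ((tested["ks_p"] < 0.05 / 40) == tested["is_key_driver"]).all()

    def test_degree_matched_null_agrees_directionally(self):
        net = _ba_network(seed=3, n=60)
        top = sorted(net.nodes, key=lambda n: -net.nodes[n]["g"])[:8]
        net.add_node("HUB", g=0.5)
        for t in top:
            net.add_edge("HUB", t)
        rng = np.random.default_rng(0)
        p_bg = ks_keydriver_test(net, "HUB", null="background")
        p_dm = ks_keydriver_test(net, "HUB", null="degree-matched",
                                 n_resample=500, rng=rng)
        assert p_bg < 0.01 and p_dm < 0.05
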