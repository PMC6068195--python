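import numpy as np
import networkx as nx
import pytest

from tissuenet import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_planted_study():
    """A compact planted study reused across unit tests (150 genes, 8-gene module)."""
    config = SimulationConfig(
        n_genes=150,
        n_variants_per_gene=(4, 10),
        planted_module_size=8,
        set_size=10,
        n_gene_sets=20,
        seed=11,
    )
    return simulate_all(config)


@pytest.fixture()
def scored_random_network():
    """Deterministic 30-node scale-free network with |N(0,1)| node scores."""

    def build(seed: int = 0, n: int = 30) -> nx.Graph:
        g = nx.barabasi_albert_graph(n, 2, seed=seed)
        g = nx.relabel_nodes(g, {i: f"N{i:03d}" for i in range(n)})
        rng = np.random.default_rng(seed)
        for node in g.nodes:
            g.nodes[node]["g"] = float(np.abs(rng.normal()))
        for a, b in g.edges:
            g.edges[a, b]["weight"] = float(rng.uniform(-1, 1))
        return g

    return build
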