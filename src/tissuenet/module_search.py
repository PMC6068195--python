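"""Greedy dense-module search on a scored tissue network.

Starting from each seed gene (a gene passing Bonferroni significance), the
search repeatedly adds the neighboring gene that most increases the module
score ``Zm = sum(g_i) / sqrt(k)`` — ``k`` the module size — and stops when
no addition improves it.  Modules grown from different seeds overlap heavily
and are merged into one combined network by node-set union.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["Module", "module_score", "grow_module", "search_all", "merge_modules"]

logger = logging.getLogger(__name__)


def module_score(scores) -> float:
    """``Zm = sum(g_i) / sqrt(k)`` for the k scores of a candidate module."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("module score of an empty gene list")
    return float(scores.sum() / np.sqrt(scores.size))


@dataclass
class Module:
    """A grown module: genes in addition order, with its score trajectory."""

    seed_gene: str
    genes: list[str]
    Zm: float
    trajectory: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.genes)


def _node_score(net: nx.Graph, node: str) -> float:
    return float(net.nodes[node].get("g", 0.0))


def _candidates(net: nx.Graph, members: set[str], order: int) -> set[str]:
    """All genes within ``order`` steps of the module, excluding members."""
    frontier = set(members)
    seen = set(members)
    for _ in range(order):
        nxt = set()
        for u in frontier:
            nxt.update(net.neighbors(u))
        nxt -= seen
        seen |= nxt
        frontier = nxt
    return seen - set(members)


def grow_module(net: nx.Graph, seed_gene: str, improvement_rate: float = 0.0,
                neighbor_order: int = 1) -> Module:
    """Grow one module greedily from ``seed_gene``.

    Each iteration scans every gene within ``neighbor_order`` steps of the
    current module and adds the single candidate maximizing the new ``Zm``,
    provided ``Zm_new > Zm_old * (1 + improvement_rate)``.  Ties are broken
    by higher gene score, then lexicographic gene id, which makes the result
    independent of edge iteration order.  Terminates because the score
    strictly increases and the module is bounded by the network.
    """
    if seed_gene not in net:
        raise KeyError(f"seed gene {seed_gene!r} not in network")
    members = [seed_gene]
    member_set = {seed_gene}
    total = _node_score(net, seed_gene)
    zm = total  # k = 1
    trajectory = [zm]
    while True:
        cands = _candidates(net, member_set, neighbor_order)
        if not cands:
            break
        k_new = len(members) + 1
        best = None
        # ascending id scan + strict comparisons: ties go to the higher-g,
        # then lexicographically-earliest candidate
        for c in sorted(cands):
            g = _node_score(net, c)
            zm_c = (total + g) / np.sqrt(k_new)
            if best is None or (zm_c, g) > (best[0], best[3]):
                best = (zm_c, c, zm_c, g)
        _, cand, zm_new, g = best
        if zm_new > zm * (1.0 + improvement_rate):
            members.append(cand)
            member_set.add(cand)
            total += g
            zm = zm_new
            trajectory.append(zm)
        else:
            break
    return Module(seed_gene=seed_gene, genes=members, Zm=zm, trajectory=trajectory)


def search_all(net: nx.Graph, seed_gene_ids, improvement_rate: float = 0.0,
               neighbor_order: int = 1) -> list[Module]:
    """Grow one module per usable seed gene.

    Seeds absent from the network are reported and skipped (the network only
    contains genes with retained coexpressed interactions, so not every
    significant gene appears in it).  Deterministic given network and
    parameters; duplicate seeds yield one module each.
    """
    seeds = list(seed_gene_ids)
    usable = [s for s in seeds if s in net]
    missing = [s for s in seeds if s not in net]
    if missing:
        logger.info("%d of %d seed genes absent from the network: %s",
                    len(missing), len(seeds), missing[:10])
    if not usable:
        warnings.warn("no seed gene present in the network; no modules grown")
        return []
    return [grow_module(net, s, improvement_rate, neighbor_order) for s in usable]


def merge_modules(modules: list[Module], net: nx.Graph) -> nx.Graph:
    """Union the modules into one combined network.

    Nodes are the union of all module gene sets with per-node provenance
    (which seeds contributed the gene); edges are the tissue-network edges
    induced on that node set, weights preserved.
    """
    if not modules:
        raise ValueError("no modules to merge")
    provenance: dict[str, list[str]] = {}
    for m in modules:
        for gene in m.genes:
            provenance.setdefault(gene, []).append(m.seed_gene)
    nodes = sorted(provenance)
    merged = nx.Graph(net.subgraph(nodes).copy())
    merged.add_nodes_from(nodes)  # keep genes even if isolated in the induced graph
    for gene in nodes:
        merged.nodes[gene].setdefault("g", float(net.nodes[gene].get("g", 0.0)))
        merged.nodes[gene].setdefault(
            "significant", bool(net.nodes[gene].get("significant", False))
        )
        merged.nodes[gene]["seeds"] = ",".join(sorted(set(provenance[gene])))
    logger.info("merged %d modules: %d nodes, %d edges, %d significant",
                len(modules), merged.number_of_nodes(), merged.number_of_edges(),
                sum(1 for n in merged if merged.nodes[n]["significant"]))
    return merged
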