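"""Calibration and recovery experiments for the whole pipeline.

These routines run the package end-to-end on synthetic studies and measure
how well it behaves where the answer is known:

* :func:`set_test_mc_agreement` — the analytic weighted-chi-squared tail
  against a brute-force Monte-Carlo oracle on random LD structures;
* :func:`null_calibration` — gene-level p-value uniformity and the absence
  of key drivers when nothing is planted;
* :func:`planted_recovery` — recall of the planted module, centroid rank of
  the planted hub and enrichment rank of the planted gene set when a causal
  module is present.

Each experiment derives per-replicate seeds from a single base seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import kstest, norm

from .coexpression import attach_scores, clean_interactions, coexpression_filter
from .enrichment import ora
from .gene_assoc import ar1_ld_source, run_gene_assoc
from .key_drivers import key_driver_scan, rank_centroids
from .module_search import merge_modules, search_all
from .quadform import wchi2_sf
from .simulate import SimulationConfig, simulate_all

__all__ = ["set_test_mc_agreement", "null_calibration", "planted_recovery",
           "run_study_stages"]


def _child_seeds(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def set_test_mc_agreement(n_sets: int = 200, n_draws: int = 10**6,
                          base_seed: int = 0) -> dict:
    """Compare the inversion tail with a Monte-Carlo oracle on random sets.

    For each replicate: a random 2-10 variant set with a random PSD LD
    matrix; the observed statistic is itself one draw from the mixture, so
    its tail probability is uniformly distributed and the Monte-Carlo
    standard error is well behaved.  Also checks that single-variant sets
    return exactly the variant's two-sided normal p.
    """
    rng = np.random.default_rng(base_seed)
    deviations = []
    n_within = 0
    for _ in range(n_sets):
        k = int(rng.integers(2, 11))
        R = np.corrcoef(rng.standard_normal((k, k + 3)))
        lam = np.linalg.eigvalsh(R)
        lam = lam[lam > 1e-10]
        T = float((lam * rng.chisquare(1, size=lam.size)).sum())
        p_hat = wchi2_sf(T, lam).p
        draws = (lam * rng.chisquare(1, size=(n_draws, lam.size))).sum(axis=1)
        p_mc = float((draws > T).mean())
        se = float(np.sqrt(max(p_mc * (1 - p_mc), 1e-12) / n_draws))
        z = abs(p_hat - p_mc) / se
        deviations.append(z)
        n_within += z < 3
    single_ok = all(
        abs(wchi2_sf(z0**2, [1.0]).p - 2 * norm.sf(abs(z0))) < 1e-12
        for z0 in rng.normal(size=50)
    )
    return {
        "n_sets": n_sets,
        "frac_within_3se": n_within / n_sets,
        "max_deviation_se": float(max(deviations)),
        "single_variant_exact": bool(single_ok),
    }


def run_study_stages(config: SimulationConfig) -> dict:
    """Run simulation plus every analysis stage in memory; return all artifacts."""
    study = simulate_all(config)
    assoc = run_gene_assoc(study.variants, study.genes,
                           ar1_ld_source(config.ld_rho))
    net = attach_scores(
        coexpression_filter(clean_interactions(study.edges), study.expression),
        assoc,
    )
    seeds = assoc.loc[assoc["significant"], "gene_id"].tolist()
    modules = search_all(net, [s for s in seeds if s in net])
    merged = merge_modules(modules, net) if modules else None
    return {"study": study, "assoc": assoc, "net": net,
            "modules": modules, "merged": merged}


def null_calibration(n_seeds: int = 20, n_genes: int = 1000,
                     base_seed: int = 0) -> dict:
    """Pipeline behaviour with no planted signal.

    Per replicate: KS uniformity of the gene p-values, and the key-driver
    count on the (score-attached) tissue network.  A replicate passes when
    the KS test accepts uniformity at alpha = 0.01 and at most one gene is
    called a key driver.
    """
    results = []
    for seed in _child_seeds(base_seed, n_seeds):
        config = SimulationConfig(n_genes=n_genes, noncentrality=0.0, seed=seed)
        stages = run_study_stages(config)
        ks_p = float(kstest(stages["assoc"]["p"], "uniform").pvalue)
        kd_net = stages["merged"] if stages["merged"] is not None else stages["net"]
        n_kd = (int(key_driver_scan(kd_net)["is_key_driver"].sum())
                if kd_net.number_of_nodes() else 0)
        results.append({"ks_p": ks_p, "n_key_drivers": n_kd,
                        "pass": ks_p > 0.01 and n_kd <= 1})
    return {
        "n_seeds": n_seeds,
        "ks_p": [r["ks_p"] for r in results],
        "n_key_drivers": [r["n_key_drivers"] for r in results],
        "pass_rate": sum(r["pass"] for r in results) / n_seeds,
        "median_ks_p": float(np.median([r["ks_p"] for r in results])),
        "max_key_drivers": max(r["n_key_drivers"] for r in results),
    }


def planted_recovery(n_seeds: int = 20, base_seed: int = 0,
                     noncentrality: float = 4.0,
                     planted_edge_corr: float = 0.9) -> dict:
    """Recovery of the planted causal module across replicate studies.

    Per replicate: recall of planted-module genes in the merged network,
    whether the planted hub ranks in the top 5% of tissue-network genes by
    weighted centroid, and whether the planted gene set is top-ranked by
    enrichment FDR.
    """
    recalls, hub_top, set_top = [], [], []
    for seed in _child_seeds(base_seed, n_seeds):
        config = SimulationConfig(noncentrality=noncentrality,
                                  planted_edge_corr=planted_edge_corr, seed=seed)
        stages = run_study_stages(config)
        truth = stages["study"].truth
        merged = stages["merged"]
        nodes = set(merged.nodes) if merged is not None else set()
        recalls.append(len(nodes & truth.planted_module) / len(truth.planted_module))

        ranking = rank_centroids(stages["net"])
        cutoff = max(1, int(np.ceil(0.05 * len(ranking))))
        in_net = truth.hub_gene in stages["net"]
        rank = (int(ranking.loc[ranking["gene_id"] == truth.hub_gene, "rank"].iloc[0])
                if in_net else len(ranking) + 1)
        hub_top.append(rank <= cutoff)

        if nodes:
            enr = ora(sorted(nodes), stages["study"].gene_sets,
                      sorted(stages["study"].genes["gene_id"]))
            set_top.append(bool(len(enr) and enr.loc[0, "set_id"] == truth.enriched_set_id))
        else:
            set_top.append(False)
    return {
        "n_seeds": n_seeds,
        "mean_recall": float(np.mean(recalls)),
        "recalls": recalls,
        "hub_top5pct_rate": sum(hub_top) / n_seeds,
        "planted_set_top_rate": sum(set_top) / n_seeds,
    }
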