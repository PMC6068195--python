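"""Over-representation analysis of a gene list against gene sets.

Hypergeometric upper-tail test of the overlap between a query list (here:
the merged network's genes) and each annotated gene set, against an explicit
background universe; Benjamini-Hochberg FDR across the tested sets; the
enrichment ratio is observed overlap over its expectation under random
draws.  The background is a required input — results are meaningless
without stating the universe the query was drawn from.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["ora", "enrichment_ratio", "filter_fdr"]


def enrichment_ratio(n_overlap: int, n_set: int, n_query: int, n_background: int) -> float:
    """Observed overlap divided by its expectation ``n_query * n_set / n_background``."""
    expected = n_query * n_set / n_background
    if expected == 0:
        raise ZeroDivisionError("expected overlap is zero (empty set or query)")
    return n_overlap / expected


def ora(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, dict],
    background: Iterable[str],
    min_set_size: int = 3,
    max_set_size: int = 2000,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each set.

    Per set: population = background size, successes = set genes in the
    background, draws = query genes in the background; p-value is
    ``P(X >= n_overlap)``.  Query genes outside the background are dropped
    with a warning; sets are restricted to the background and skipped when
    their restricted size falls outside ``[min_set_size, max_set_size]``.
    FDR is Benjamini-Hochberg across the tested sets.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene list")
    outside = query - background
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the background "
                      "were dropped")
        query &= background
        if not query:
            raise ValueError("no query gene lies in the background")

    M = len(background)
    N = len(query)
    rows = []
    for set_id, rec in gene_sets.items():
        genes = set(rec["genes"]) & background
        K = len(genes)
        if not (min_set_size <= K <= max_set_size):
            continue
        overlap = query & genes
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append({
            "set_id": set_id,
            "description": rec.get("description", ""),
            "n_set": K,
            "n_query": N,
            "n_overlap": k,
            "expected": N * K / M,
            "ratio": enrichment_ratio(k, K, N, M),
            "p": min(p, 1.0),
            "overlap_genes": ";".join(sorted(overlap)),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out.reindex(columns=["set_id", "description", "n_set", "n_query",
                                    "n_overlap", "expected", "ratio", "p", "fdr",
                                    "overlap_genes"])
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return out[["set_id", "description", "n_set", "n_query", "n_overlap",
                "expected", "ratio", "p", "fdr", "overlap_genes"]]


def filter_fdr(results: pd.DataFrame, fdr_max: float = 0.1) -> pd.DataFrame:
    """Rows with ``fdr`` strictly below ``fdr_max``, sorted by p-value."""
    if results.empty:
        return results
    out = results[results["fdr"] < fdr_max]
    return out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
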