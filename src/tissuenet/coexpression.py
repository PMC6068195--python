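"""Tissue-specific interaction network construction.

A reported protein-interaction edge list is cleaned (self-interactions and
non-human edges removed, duplicates collapsed) and then intersected with
tissue coexpression: each surviving edge must connect genes whose normalized
expression correlates above a threshold in the target tissue.  The result is
an undirected graph whose edge weights are the signed correlations and whose
nodes carry the gene-level association score ``g`` when one is supplied.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "clean_interactions",
    "rank_inverse_normal",
    "coexpression_filter",
    "network_summary",
    "attach_scores",
]

logger = logging.getLogger(__name__)

HUMAN_TAXON = "9606"


def clean_interactions(raw: pd.DataFrame, human_taxon: str = HUMAN_TAXON) -> pd.DataFrame:
    """Drop self-loops and non-human edges; canonicalise and deduplicate.

    Edges are unordered: each pair is stored with ``gene_a < gene_b``.
    Taxon filtering only applies when taxon columns are present; taxon ids
    may carry a ``taxid:`` prefix (MITAB style).
    """
    df = raw.copy()
    n0 = len(df)
    df = df[df["gene_a"] != df["gene_b"]]

    def _taxon(col: pd.Series) -> pd.Series:
        return col.astype(str).str.replace("taxid:", "", regex=False).str.split("(").str[0]

    if {"taxon_a", "taxon_b"} <= set(df.columns):
        ok = (_taxon(df["taxon_a"]) == str(human_taxon)) & (
            _taxon(df["taxon_b"]) == str(human_taxon)
        )
        df = df[ok]
    a = df[["gene_a", "gene_b"]].min(axis=1)
    b = df[["gene_a", "gene_b"]].max(axis=1)
    out = pd.DataFrame({"gene_a": a, "gene_b": b}).drop_duplicates()
    out = out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    logger.info("interaction cleaning: %d raw rows -> %d edges", n0, len(out))
    return out


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, ``Phi^-1((rank - 0.5) / n)``.

    Average ranks for ties; maps any marginal distribution onto normal
    quantiles, robustifying Pearson correlation against outliers.
    """
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.5) / len(values))


def _normalize_expression(expr: pd.DataFrame, normalization: str) -> pd.DataFrame:
    if normalization == "rank-inverse-normal":
        mat = np.apply_along_axis(rank_inverse_normal, 1, expr.to_numpy(dtype=float))
        return pd.DataFrame(mat, index=expr.index, columns=expr.columns)
    if normalization in ("none", "pearson"):
        return expr.astype(float)
    if normalization == "spearman":  # rank, then plain Pearson == Spearman
        mat = np.apply_along_axis(lambda v: rankdata(v, method="average"), 1,
                                  expr.to_numpy(dtype=float))
        return pd.DataFrame(mat, index=expr.index, columns=expr.columns)
    raise ValueError(f"unknown normalization: {normalization!r}")


def _expression_qc(expr: pd.DataFrame, min_nonzero_frac: float = 0.5) -> pd.DataFrame:
    """Drop zero-variance genes and genes expressed in <50% of samples."""
    mat = expr.to_numpy(dtype=float)
    keep = (mat.std(axis=1) > 0) & ((mat != 0).mean(axis=1) >= min_nonzero_frac)
    n_drop = int((~keep).sum())
    if n_drop:
        warnings.warn(f"expression QC removed {n_drop} gene(s) "
                      "(zero variance or mostly-zero expression)")
    return expr.loc[keep]


def coexpression_filter(
    edges: pd.DataFrame,
    expr: pd.DataFrame,
    threshold: float = 0.25,
    normalization: str = "rank-inverse-normal",
    use_abs: bool = True,
    min_nonzero_frac: float = 0.5,
) -> nx.Graph:
    """Retain interaction edges whose genes coexpress above ``threshold``.

    Per edge, both genes' expression vectors are normalized across samples
    (default: rank-based inverse normal transform) and their Pearson
    correlation ``r`` is computed; the edge survives iff ``|r| > threshold``
    (strictly; or signed ``r > threshold`` with ``use_abs=False``) and keeps
    the signed ``r`` as its weight.  Edges touching genes absent from the
    expression matrix, or failing expression QC, are dropped and counted.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 expression samples for correlation")
    expr = _expression_qc(expr, min_nonzero_frac)
    normed = _normalize_expression(expr, normalization)
    mat = normed.to_numpy(dtype=float)
    mat = (mat - mat.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(mat, axis=1)
    index = {g: i for i, g in enumerate(normed.index)}

    net = nx.Graph()
    n_missing = 0
    for row in edges.itertuples(index=False):
        ia = index.get(row.gene_a)
        ib = index.get(row.gene_b)
        if ia is None or ib is None:
            n_missing += 1
            continue
        denom = norms[ia] * norms[ib]
        if denom == 0:
            n_missing += 1
            continue
        r = float(mat[ia] @ mat[ib] / denom)
        retained = abs(r) > threshold if use_abs else r > threshold
        if retained:
            net.add_edge(row.gene_a, row.gene_b, weight=r)
    if n_missing:
        logger.info("coexpression filter: %d edge(s) dropped for missing/QC-failed genes",
                    n_missing)
    logger.info("coexpression filter: %d of %d edges retained (threshold %g, %s)",
                net.number_of_edges(), len(edges), threshold,
                "absolute" if use_abs else "signed")
    return net


def attach_scores(net: nx.Graph, assoc: pd.DataFrame) -> nx.Graph:
    """Attach gene scores and significance flags as node attributes.

    Network genes without an association result get ``g = 0`` and are
    flagged ``scored = False``: they can join modules only by bridging
    value, never by score.
    """
    scores = assoc.set_index("gene_id")
    for node in net.nodes:
        if node in scores.index:
            net.nodes[node]["g"] = float(scores.loc[node, "g"])
            net.nodes[node]["significant"] = bool(scores.loc[node, "significant"])
            net.nodes[node]["scored"] = True
        else:
            net.nodes[node]["g"] = 0.0
            net.nodes[node]["significant"] = False
            net.nodes[node]["scored"] = False
    return net


def network_summary(net: nx.Graph) -> dict:
    """Node/edge counts, significant-node count and a degree table."""
    degrees = dict(net.degree())
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_significant": sum(
            1 for n in net.nodes if net.nodes[n].get("significant", False)
        ),
        "degree": dict(sorted(degrees.items())),
    }
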