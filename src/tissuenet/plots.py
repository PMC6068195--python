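"""Diagnostic plots for gene-level association results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["manhattan", "qq", "qq_slope"]


def manhattan(assoc: pd.DataFrame, genes: pd.DataFrame | None = None,
              threshold: float | None = None, ax=None):
    """Manhattan plot of gene-level -log10 p along the genome.

    ``genes`` supplies positions (gene_id, chrom, start); without it, genes
    are plotted in chromosome-then-table order.  ``threshold`` draws the
    Bonferroni line at ``-log10(threshold)``.
    """
    df = assoc.copy()
    if genes is not None:
        df = df.merge(genes[["gene_id", "start"]], on="gene_id", how="left")
        df = df.sort_values(["chrom", "start"], kind="mergesort")
    else:
        df = df.sort_values("chrom", kind="mergesort")
    df = df.reset_index(drop=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    colors = {c: f"C{i % 2}" for i, c in enumerate(pd.unique(df["chrom"]))}
    ax.scatter(df.index, -np.log10(df["p"]), s=6,
               c=[colors[c] for c in df["chrom"]])
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", linestyle="--", lw=1)
    ax.set_xlabel("genes (genomic order)")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax


def qq(pvals, ax=None):
    """Q-Q plot of observed vs expected -log10 p under uniformity."""
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)  # both sorted descending: smallest p first
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(expected, observed, s=6)
    lim = max(expected.max(), observed.max()) if n else 1.0
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    ax.set_xlabel(r"expected $-\log_{10} P$")
    ax.set_ylabel(r"observed $-\log_{10} P$")
    return ax


def qq_slope(pvals) -> float:
    """Least-squares slope of observed on expected -log10 p (no intercept).

    Near 1.0 for a well-calibrated null, inflated above 1 under
    miscalibration — a genomic-control-style diagnostic.
    """
    p = np.sort(np.asarray(pvals, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no p-values")
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return float(expected @ observed / (expected @ expected))
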