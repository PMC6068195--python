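"""Gene-level association from GWAS variant summary statistics.

Collapses variant z-scores into a per-gene set test: ``T = sum_j z_j**2``
with null distribution ``sum_i lambda_i chi2_1`` where ``lambda_i`` are the
eigenvalues of the window's LD correlation matrix.  Gene p-values are mapped
to non-negative association scores ``g = Phi^-1(1 - p)`` used downstream for
module search and key-driver ranking, and genes passing the Bonferroni
threshold ``alpha / n_tested`` are flagged as seed genes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .quadform import wchi2_sf

__all__ = [
    "filter_common",
    "map_variants_to_genes",
    "ld_from_panel",
    "ar1_corr",
    "ar1_ld_source",
    "panel_ld_source",
    "matrix_ld_source",
    "set_test",
    "gene_score",
    "bonferroni_threshold",
    "run_gene_assoc",
]

logger = logging.getLogger(__name__)

# p-values below this are floored before the normal quantile so scores stay
# finite; the matching score cap is Phi^-1(1 - 1e-300) ~= 37.0.
P_FLOOR = 1e-300
G_CAP = float(norm.isf(P_FLOOR))

# LD sources are callables: (gene_id, ordered variant ids) -> correlation matrix
LDSource = Callable[[str, list[str]], np.ndarray]


def filter_common(variants: pd.DataFrame, maf_min: float = 0.01) -> pd.DataFrame:
    """Keep variants with minor allele frequency >= ``maf_min`` (boundary inclusive)."""
    if "freq" not in variants.columns:
        raise ValueError("variant table is missing the 'freq' column")
    kept = variants[variants["freq"] >= maf_min].reset_index(drop=True)
    logger.info("MAF filter >= %g: kept %d of %d variants", maf_min, len(kept), len(variants))
    return kept


def map_variants_to_genes(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = 50_000,
) -> dict[str, list[str]]:
    """Assign variants to gene windows ``[start - flank, end + flank]`` (closed).

    Gene coordinates are 1-based closed intervals (BED input is converted on
    read).  A variant inside several overlapping windows belongs to every one
    of them; genes with no variants are omitted.  Within a window, variants
    are ordered by position.

    Returns a mapping gene_id -> ordered variant-id list.
    """
    var_chroms = set(variants["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    if var_chroms and gene_chroms and not (var_chroms & gene_chroms):
        counts_v = variants["chrom"].value_counts().to_dict()
        counts_g = genes["chrom"].value_counts().to_dict()
        raise ValueError(
            "no shared chromosome names between variants and genes; "
            f"variant chroms: {counts_v}; gene chroms: {counts_g}"
        )

    if variants["variant_id"].duplicated().any():
        n_dup = int(variants["variant_id"].duplicated().sum())
        warnings.warn(f"{n_dup} duplicate variant ids: keeping first occurrence")
        variants = variants.drop_duplicates("variant_id", keep="first")

    windows: dict[str, list[str]] = {}
    v_sorted = variants.sort_values(["chrom", "pos"], kind="mergesort")
    by_chrom = {str(c): grp for c, grp in v_sorted.groupby(variants["chrom"].astype(str))}
    for row in genes.itertuples(index=False):
        grp = by_chrom.get(str(row.chrom))
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        lo = np.searchsorted(pos, row.start - flank, side="left")
        hi = np.searchsorted(pos, row.end + flank, side="right")
        if hi > lo:
            windows[str(row.gene_id)] = grp["variant_id"].iloc[lo:hi].tolist()
    return windows


def ld_from_panel(dosages: pd.DataFrame, variant_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Pearson LD from a reference dosage panel (samples x variants).

    Monomorphic variants are dropped with a warning; the returned id list
    reflects the columns actually used.
    """
    if dosages.shape[0] < 2:
        raise ValueError("LD panel needs at least 2 samples")
    present = [v for v in variant_ids if v in dosages.columns]
    mat = dosages[present].to_numpy(dtype=float)
    sd = mat.std(axis=0)
    mono = sd == 0.0
    if mono.any():
        dropped = [v for v, m in zip(present, mono) if m]
        warnings.warn(f"dropping {len(dropped)} monomorphic variant(s): {dropped[:5]}")
        present = [v for v, m in zip(present, mono) if not m]
        mat = mat[:, ~mono]
    if not present:
        raise ValueError("no polymorphic variants left in panel")
    R = np.corrcoef(mat, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return R, present


def ar1_corr(k: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R[i, j] = rho**|i - j|."""
    if not (0.0 <= abs(rho) < 1.0):
        raise ValueError("AR(1) parameter must satisfy |rho| < 1")
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def ar1_ld_source(rho: float) -> LDSource:
    """LD source with known AR(1) structure (matches the synthetic generator)."""

    def source(gene_id: str, variant_ids: list[str]) -> np.ndarray:
        return ar1_corr(len(variant_ids), rho)

    return source


def panel_ld_source(dosages: pd.DataFrame) -> LDSource:
    """LD source backed by a reference genotype/dosage panel."""

    def source(gene_id: str, variant_ids: list[str]) -> np.ndarray:
        R, used = ld_from_panel(dosages, variant_ids)
        if used != variant_ids:
            raise ValueError(
                f"panel lacks (or drops) variants for gene {gene_id}: "
                f"expected {len(variant_ids)}, usable {len(used)}"
            )
        return R

    return source


def matrix_ld_source(matrices: Mapping[str, np.ndarray]) -> LDSource:
    """LD source from precomputed per-gene correlation matrices."""

    def source(gene_id: str, variant_ids: list[str]) -> np.ndarray:
        R = np.asarray(matrices[gene_id], dtype=float)
        if R.shape != (len(variant_ids), len(variant_ids)):
            raise ValueError(f"LD matrix shape mismatch for gene {gene_id}")
        return R

    return source


def set_test(z: np.ndarray, R: np.ndarray) -> tuple[float, np.ndarray, float, str]:
    """Set-based test of a variant window.

    Returns ``(T, lambdas, p, method)`` where ``T = sum z**2``, ``lambdas``
    are the eigenvalues of ``R`` and ``p`` is the upper tail of the weighted
    chi-squared mixture.
    """
    z = np.asarray(z, dtype=float)
    R = np.asarray(R, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("z must be a non-empty 1-d vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    if R.shape != (z.size, z.size):
        raise ValueError(f"dimension mismatch: {z.size} z-scores vs LD {R.shape}")
    T = float(np.sum(z**2))
    lambdas = np.linalg.eigvalsh(R)
    if np.min(lambdas) < -1e-6:
        raise ValueError("LD matrix is not positive semi-definite")
    res = wchi2_sf(T, lambdas)
    return T, lambdas, res.p, res.method


def gene_score(p: float, nonnegative: bool = True) -> float:
    """Map a gene p-value to the score ``g = Phi^-1(1 - p)``.

    ``p`` is floored at 1e-300 (score cap ~37.0).  With ``nonnegative``
    (default), scores for p > 0.5 are floored at 0 so that module scores are
    never rewarded for sub-null genes; pass ``nonnegative=False`` for the raw
    signed quantile.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value out of (0, 1]: {p}")
    g = float(norm.isf(max(p, P_FLOOR)))
    g = min(g, G_CAP)
    return max(g, 0.0) if nonnegative else g


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def run_gene_assoc(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    ld_source: LDSource,
    flank: int = 50_000,
    alpha: float = 0.05,
    maf_min: float | None = 0.01,
    nonnegative_scores: bool = True,
) -> pd.DataFrame:
    """Run the gene-level association stage.

    Parameters
    ----------
    variants
        Variant summary statistics with columns ``variant_id, chrom, pos,
        freq, z, p`` (``p`` recomputed from ``z`` if absent).
    genes
        Gene annotation with columns ``gene_id, chrom, start, end``
        (1-based closed coordinates; see :func:`tissuenet.io.read_genes_bed`).
    ld_source
        Callable ``(gene_id, variant_ids) -> correlation matrix``.
    flank
        Window extension in bp on each side of the gene body.
    alpha
        Family-wise error target; the significance flag uses
        ``alpha / n_tested_genes``.
    maf_min
        Minor-allele-frequency filter applied first (``None`` disables).

    Returns one row per gene with >= 1 variant: gene_id, chrom, n_variants,
    T, p, g, best_variant, best_variant_p, method, significant.
    """
    if maf_min is not None:
        variants = filter_common(variants, maf_min)
    windows = map_variants_to_genes(variants, genes, flank=flank)
    vtab = variants.set_index("variant_id")
    if "p" not in vtab.columns:
        vtab = vtab.assign(p=2.0 * norm.sf(np.abs(vtab["z"].to_numpy())))
    gene_meta = genes.set_index("gene_id")

    rows = []
    for gene_id, vids in windows.items():
        z = vtab.loc[vids, "z"].to_numpy(dtype=float)
        R = np.asarray(ld_source(gene_id, vids), dtype=float)
        T, lambdas, p, method = set_test(z, R)
        vp = vtab.loc[vids, "p"].to_numpy(dtype=float)
        best = int(np.argmin(vp))
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": gene_meta.loc[gene_id, "chrom"],
                "n_variants": len(vids),
                "T": T,
                "p": p,
                "g": gene_score(p, nonnegative=nonnegative_scores),
                "best_variant": vids[best],
                "best_variant_p": float(vp[best]),
                "method": method,
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        warnings.warn("no gene received any variant; empty association table")
        return result.reindex(
            columns=[
                "gene_id", "chrom", "n_variants", "T", "p", "g",
                "best_variant", "best_variant_p", "method", "significant",
            ]
        )
    threshold = bonferroni_threshold(alpha, len(result))
    result["significant"] = result["p"] < threshold
    result = result.sort_values("p", kind="mergesort").reset_index(drop=True)
    logger.info(
        "gene association: %d genes tested, %d significant at %g",
        len(result), int(result["significant"].sum()), threshold,
    )
    return result
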