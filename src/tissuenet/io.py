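"""Readers and writers for the pipeline's standard text formats.

Variants and expression are plain TSV, gene annotation is BED (0-based
half-open on disk, converted to 1-based closed in memory), gene sets are
GMT, interaction edges are either plain two-column TSV or a MITAB-like
layout with taxon columns, and networks round-trip through GraphML via
networkx.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "read_variants",
    "write_variants",
    "read_genes_bed",
    "write_genes_bed",
    "read_expression",
    "write_expression",
    "read_edges",
    "write_edges",
    "read_gmt",
    "write_gmt",
    "read_background",
    "write_network_graphml",
    "read_network_graphml",
    "write_network_edgelist",
    "write_json",
    "read_json",
]

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "a1", "a2", "freq", "z", "p"]

# GCTA .ma-style headers mapped onto the native schema
_MA_ALIASES = {
    "SNP": "variant_id",
    "snp": "variant_id",
    "A1": "a1",
    "A2": "a2",
    "freq": "freq",
    "b": "beta",
    "se": "se",
    "p": "p",
    "N": "n",
}


def read_variants(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a variant summary-statistics TSV.

    ``column_map`` renames input headers to the native schema
    (variant_id, chrom, pos, a1, a2, freq, z, p); GCTA .ma-style headers are
    recognised automatically.  ``z`` is derived from beta/se when absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    rename = dict(_MA_ALIASES)
    if column_map:
        rename.update(column_map)
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    if "z" not in df.columns and {"beta", "se"} <= set(df.columns):
        df["z"] = df["beta"] / df["se"]
    missing = {"variant_id", "chrom", "pos", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_variants(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    """Read gene annotation BED (chrom, start, end, gene_id).

    BED is 0-based half-open; in-memory coordinates are 1-based closed, so
    ``start = bed_start + 1`` and ``end = bed_end``.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene_id"], dtype={0: str},
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df[["gene_id", "chrom", "start", "end"]]


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based closed gene bodies as 0-based half-open BED."""
    out = genes.assign(bed_start=genes["start"] - 1)
    out[["chrom", "bed_start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read an interaction edge list.

    Accepts plain two-column TSV (gene_a, gene_b, headered or not) or a
    MITAB-like file with ``taxon_a``/``taxon_b`` columns.  Unparseable rows
    are counted and skipped, not fatal.
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    has_header = str(first.iloc[0, 0]).lower() in {"gene_a", "interactor_a", "#id_a", "ida"}
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype=str)
    if not has_header:
        names = ["gene_a", "gene_b", "source", "taxon_a", "taxon_b"][: df.shape[1]]
        df.columns = names
    df = df.rename(columns={"interactor_a": "gene_a", "interactor_b": "gene_b",
                            "ida": "gene_a", "idb": "gene_b"})
    bad = df["gene_a"].isna() | df["gene_b"].isna()
    if bad.any():
        df = df[~bad]
    return df.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file into {set_id: {"description": ..., "genes": set}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = {"description": parts[1], "genes": set(parts[2:])}
    return sets


def write_gmt(sets: Mapping[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, rec in sets.items():
            genes = "\t".join(sorted(rec["genes"]))
            fh.write(f"{set_id}\t{rec.get('description', '')}\t{genes}\n")


def read_background(path: str | Path) -> set[str]:
    """Read a background gene universe: one gene id per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_network_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_network_edgelist(net: nx.Graph, path: str | Path) -> None:
    rows = [
        {"gene_a": a, "gene_b": b, "weight": round(d.get("weight", 1.0), 10)}
        for a, b, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
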