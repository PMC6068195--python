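"""End-to-end orchestration: association -> network -> modules -> drivers -> ORA.

A single :class:`PipelineConfig` names every input file and parameter; the
run writes all stage tables plus a manifest recording parameters, input
checksums and output checksums, so a rerun with the same config and inputs
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .coexpression import attach_scores, clean_interactions, coexpression_filter, network_summary
from .enrichment import filter_fdr, ora
from .gene_assoc import ar1_ld_source, bonferroni_threshold, panel_ld_source, run_gene_assoc
from .key_drivers import key_driver_scan
from .module_search import merge_modules, search_all

__all__ = ["PipelineConfig", "run_pipeline", "flank_sensitivity"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All file paths and tuning parameters for one pipeline run."""

    variants: str
    genes: str
    edges: str
    expression: str
    gene_sets: str
    out_dir: str
    background: str | None = None  # default: all annotated genes
    # gene association
    flank: int = 50_000
    maf_min: float = 0.01
    alpha: float = 0.05
    ld_mode: str = "ar1"  # "ar1" | "panel"
    ld_rho: float = 0.5
    ld_panel: str | None = None
    # coexpression network
    coexpr_threshold: float = 0.25
    normalization: str = "rank-inverse-normal"
    use_abs: bool = True
    # module search
    improvement_rate: float = 0.0
    neighbor_order: int = 1
    # key drivers
    kd_alpha: float = 0.05
    kd_null: str = "background"
    min_neighbors: int = 3
    # enrichment
    fdr_max: float = 0.1
    # run control
    seed: int = 0
    log_level: str = "INFO"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min out of range")
        if not (0.0 < self.alpha <= 1.0 and 0.0 < self.kd_alpha <= 1.0):
            raise ValueError("alpha levels must lie in (0, 1]")
        if not (0.0 <= self.coexpr_threshold < 1.0):
            raise ValueError("coexpr_threshold out of range")
        if self.neighbor_order not in (1, 2):
            raise ValueError("neighbor_order must be 1 or 2")
        if self.ld_mode not in ("ar1", "panel"):
            raise ValueError("ld_mode must be 'ar1' or 'panel'")
        if self.ld_mode == "panel" and not self.ld_panel:
            raise ValueError("ld_mode 'panel' requires ld_panel")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "variants": self.variants,
            "genes": self.genes,
            "edges": self.edges,
            "expression": self.expression,
            "gene_sets": self.gene_sets,
        }
        if self.background:
            paths["background"] = self.background
        if self.ld_panel:
            paths["ld_panel"] = self.ld_panel
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages in order and write every table plus a manifest.

    Returns the run directory.  Missing input files are reported, by name,
    before any computation starts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    missing = [f"{k}: {v}" for k, v in config.input_paths().items()
               if not Path(v).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + "; ".join(missing))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    summary: dict[str, object] = {}

    variants = io.read_variants(config.variants)
    genes = io.read_genes_bed(config.genes)
    raw_edges = io.read_edges(config.edges)
    expr = io.read_expression(config.expression)
    gene_sets = io.read_gmt(config.gene_sets)
    background = (io.read_background(config.background) if config.background
                  else set(genes["gene_id"]))

    if config.ld_mode == "panel":
        ld_source = panel_ld_source(pd.read_csv(config.ld_panel, sep="\t"))
    else:
        ld_source = ar1_ld_source(config.ld_rho)

    # 1. gene-level association
    assoc = _stage("gene_assoc")(run_gene_assoc)(
        variants, genes, ld_source, flank=config.flank, alpha=config.alpha,
        maf_min=config.maf_min,
    )
    outputs["gene_assoc"] = out / "gene_assoc.tsv"
    assoc.to_csv(outputs["gene_assoc"], sep="\t", index=False, float_format="%.10g")
    summary["n_genes_tested"] = int(len(assoc))
    summary["n_significant_genes"] = int(assoc["significant"].sum()) if len(assoc) else 0
    summary["bonferroni_threshold"] = (
        bonferroni_threshold(config.alpha, len(assoc)) if len(assoc) else None
    )

    # 2. tissue-specific coexpression network
    def _network():
        cleaned = clean_interactions(raw_edges)
        net = coexpression_filter(cleaned, expr, threshold=config.coexpr_threshold,
                                  normalization=config.normalization,
                                  use_abs=config.use_abs)
        return attach_scores(net, assoc)

    net = _stage("coexpression_network")(_network)()
    outputs["network_edges"] = out / "tissue_network.tsv"
    io.write_network_edgelist(net, outputs["network_edges"])
    outputs["network_graphml"] = out / "tissue_network.graphml"
    io.write_network_graphml(net, outputs["network_graphml"])
    net_sum = network_summary(net)
    summary["tissue_network"] = {k: net_sum[k] for k in ("n_nodes", "n_edges", "n_significant")}

    # 3. dense-module search from Bonferroni-significant seeds
    seeds = assoc.loc[assoc["significant"], "gene_id"].tolist() if len(assoc) else []
    modules = _stage("module_search")(search_all)(
        net, seeds, improvement_rate=config.improvement_rate,
        neighbor_order=config.neighbor_order,
    )
    outputs["modules"] = out / "modules.tsv"
    pd.DataFrame(
        [{"seed_gene": m.seed_gene, "k": m.k, "Zm": m.Zm,
          "genes": ",".join(m.genes)} for m in modules],
        columns=["seed_gene", "k", "Zm", "genes"],
    ).to_csv(outputs["modules"], sep="\t", index=False, float_format="%.10g")

    if modules:
        merged = _stage("merge_modules")(merge_modules)(modules, net)
        outputs["merged_edges"] = out / "merged_network.tsv"
        io.write_network_edgelist(merged, outputs["merged_edges"])
        outputs["merged_graphml"] = out / "merged_network.graphml"
        io.write_network_graphml(merged, outputs["merged_graphml"])
        merged_sum = network_summary(merged)
        summary["merged_network"] = {k: merged_sum[k]
                                     for k in ("n_nodes", "n_edges", "n_significant")}
        kd_net = merged
        summary["key_driver_network"] = "merged"
    else:
        # no seeds (e.g. a null run): scan the full tissue network instead
        kd_net = net
        summary["merged_network"] = None
        summary["key_driver_network"] = "tissue"

    # 4. key drivers + weighted centroids
    rng = np.random.default_rng(config.seed)
    drivers = _stage("key_drivers")(key_driver_scan)(
        kd_net, alpha=config.kd_alpha, min_neighbors=config.min_neighbors,
        null=config.kd_null, rng=rng,
    )
    if not drivers.empty:
        drivers = drivers.copy()
        drivers["rank"] = (
            drivers["centroid"].rank(ascending=False, method="first").astype(int)
        )
    outputs["key_drivers"] = out / "key_drivers.tsv"
    drivers.to_csv(outputs["key_drivers"], sep="\t", index=False, float_format="%.10g")
    summary["n_key_drivers"] = int(drivers["is_key_driver"].sum()) if len(drivers) else 0

    # 5. over-representation of the (merged) network genes
    query = sorted(kd_net.nodes)
    if query:
        enr = _stage("enrichment")(ora)(query, gene_sets, background)
        outputs["enrichment"] = out / "enrichment.tsv"
        enr.to_csv(outputs["enrichment"], sep="\t", index=False, float_format="%.10g")
        sig = filter_fdr(enr, config.fdr_max)
        outputs["enrichment_significant"] = out / "enrichment_significant.tsv"
        sig.to_csv(outputs["enrichment_significant"], sep="\t", index=False,
                   float_format="%.10g")
        summary["n_enriched_sets"] = int(len(sig))
    else:
        summary["n_enriched_sets"] = 0

    if config.make_plots:
        from . import plots  # matplotlib import deferred to runs that want figures

        ax = plots.manhattan(assoc, genes, summary["bonferroni_threshold"])
        ax.figure.savefig(out / "manhattan.png", dpi=150, bbox_inches="tight")
        ax = plots.qq(assoc["p"])
        ax.figure.savefig(out / "qq.png", dpi=150, bbox_inches="tight")
        outputs["manhattan"] = out / "manhattan.png"
        outputs["qq"] = out / "qq.png"

    manifest = {
        "parameters": dataclasses.asdict(config),
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                   for k, v in config.input_paths().items()},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in outputs.items()},
        "summary": summary,
    }
    io.write_json(manifest, out / "manifest.json")
    return out


def flank_sensitivity(variants: pd.DataFrame, genes: pd.DataFrame, ld_source,
                      flank_a: int = 50_000, flank_b: int = 100_000,
                      **kwargs) -> float:
    """R^2 between gene -log10 p-values at two window sizes.

    Reruns the gene-association stage at both flanks and correlates the
    -log10 p of genes tested in both runs — a sensitivity check on how much
    the window width drives the gene-level signal.
    """
    a = run_gene_assoc(variants, genes, ld_source, flank=flank_a, **kwargs)
    b = run_gene_assoc(variants, genes, ld_source, flank=flank_b, **kwargs)
    joined = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    if len(joined) < 3:
        raise ValueError("fewer than 3 genes tested at both flanks")
    la = -np.log10(joined["p_a"].to_numpy())
    lb = -np.log10(joined["p_b"].to_numpy())
    return float(np.corrcoef(la, lb)[0, 1] ** 2)
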