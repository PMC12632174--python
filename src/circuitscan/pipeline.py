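"""End-to-end orchestration: one config, staged outputs, a run manifest.

Stage order follows the analysis workflow: QC → log transform → consensus
HVG → PCA/kNN → Leiden → annotation → differential expression → gene-set
scoring → induced connectome → ligand activity → circuit report. Every
stage writes its outputs under the run directory and records a SHA-256
hash in the manifest; every stage is deterministic given the config, so a
rerun with the same config and seed reproduces identical hashes and any
stage can be recomputed from the cached upstream files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circuits as circ
from . import cluster as clu
from . import dge as dge_mod
from . import genesets as gs
from . import io as cio
from . import qc as qc_mod

__all__ = ["PipelineConfig", "run_pipeline", "export_toxatlas_tables", "stage_seed"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the reference thresholds."""

    counts_dir: str = ""
    truth_path: str = ""
    lr_path: str = ""
    prior_path: str = ""
    gmt_path: str = ""
    outdir: str = "circuitscan_run"
    seed: int = 0
    # QC
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    remove_doublets: bool = False
    normalize: str = "cp10k"  # or "none" (bare log1p)
    # clustering
    n_hvg: int = 2000
    n_pcs: int = 50
    knn_k: int = 15
    resolution: float = 1.0
    resolution_fine: float = 0.8
    # DGE
    dge: dge_mod.DGEThresholds = field(default_factory=dge_mod.DGEThresholds)
    # ligand filters
    sender_fraction: float = 0.10
    pcc_min: float = 0.05
    # scoring
    score_genes: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        qc_kwargs = raw.pop("qc", {})
        dge_kwargs = raw.pop("dge", {})
        cfg = cls(**raw)
        if qc_kwargs:
            cfg.qc = qc_mod.QCThresholds(**qc_kwargs)
        if dge_kwargs:
            cfg.dge = dge_mod.DGEThresholds(**dge_kwargs)
        return cfg

    def validate(self) -> None:
        for attr in ("counts_dir",):
            if not getattr(self, attr):
                raise ValueError(f"config is missing required path: {attr}")
            if not Path(getattr(self, attr)).exists():
                raise ValueError(f"path does not exist: {getattr(self, attr)}")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.stages = []

    def record(self, name: str, outputs, seed, t0: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "seed": seed,
                "wall_time_s": round(time.time() - t0, 3),
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            }
        )
        self.path.write_text(json.dumps({"stages": self.stages}, indent=1))


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns ``(manifest dict, outputs dict)``.

    ``outputs`` holds the in-memory products (AnnData, tables, connectomes)
    for callers who continue in Python; everything is also on disk under
    ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json")
    results = {}

    adata = cio.read_counts(config.counts_dir)
    if "treatment" in adata.obs and "sham" not in set(adata.obs["treatment"]):
        raise ValueError('treatment labels must include "sham"')
    truth = cio.read_truth(config.truth_path) if config.truth_path else None

    # ---- QC ----------------------------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "qc")
    adata = qc_mod.filter_genes(adata, config.qc)
    adata = qc_mod.filter_cells(adata, config.qc)
    n_before = adata.n_obs
    if config.remove_doublets:
        obs_scores, sim_scores = qc_mod.detect_doublets(adata, seed=seed)
        thr = config.qc.doublet_score_threshold
        if thr == "auto":
            thr = qc_mod.auto_doublet_threshold(sim_scores)
        keep = obs_scores < thr
        adata = adata[keep].copy()
        log.info("doublet removal: %d -> %d cells (threshold %.3f)",
                 n_before, adata.n_obs, thr)
    adata = qc_mod.lognormalize(
        adata, target_sum=None if config.normalize == "none" else 1e4
    )
    qc_report = outdir / "qc_report.tsv"
    adata.obs.to_csv(qc_report, sep="\t")
    manifest.record("qc", [qc_report], seed, t0)
    results["adata"] = adata

    # ---- clustering + annotation -------------------------------------------
    t0 = time.time()
    seed = stage_seed(config.seed, "cluster")
    hv = clu.select_hvgs_consensus(adata, n_top=config.n_hvg)
    clu.embed_and_graph(adata, hv.consensus, n_pcs=config.n_pcs,
                        k=config.knn_k, seed=seed)
    labels = clu.cluster_leiden(adata.obsp["connectivities"],
                                resolution=config.resolution, seed=seed)
    if truth is not None:
        reference = clu.default_marker_reference(truth)
        clu.annotate_types(adata, labels, reference, n_top_hvg=config.n_hvg,
                           resolution_fine=config.resolution_fine,
                           k=config.knn_k, seed=seed)
    else:
        adata.obs["cluster"] = pd.Categorical(labels.astype(str))
        if "cell_type" not in adata.obs:
            adata.obs["cell_type"] = adata.obs["cluster"]
    markers = clu.rank_markers_wilcoxon(adata, adata.obs["cell_type"].to_numpy())
    markers_path = outdir / "markers.tsv"
    markers.to_csv(markers_path, sep="\t", index=False)
    meta_path = outdir / "cell_meta.tsv"
    adata.obs.to_csv(meta_path, sep="\t")
    manifest.record("cluster", [markers_path, meta_path], seed, t0)
    results["markers"] = markers

    # ---- differential expression -------------------------------------------
    t0 = time.time()
    dge = dge_mod.dge_per_celltype(adata, config.dge)
    summary = dge_mod.effect_size_summary(dge)
    dge_path = outdir / "dge.tsv"
    summary_path = outdir / "effect_size_summary.tsv"
    dge.to_csv(dge_path, sep="\t", index=False)
    summary.to_csv(summary_path, sep="\t", index=False)
    manifest.record("dge", [dge_path, summary_path], config.seed, t0)
    results["dge"], results["effect_summary"] = dge, summary

    # ---- gene-set scoring ---------------------------------------------------
    if config.gmt_path:
        t0 = time.time()
        seed = stage_seed(config.seed, "score")
        sets = cio.read_gmt(config.gmt_path)
        scores = {
            name: gs.score_gene_set(adata, genes, seed=seed)
            for name, genes in sets.items()
        }
        score_df = pd.DataFrame(scores, index=adata.obs_names)
        score_path = outdir / "signature_scores.tsv"
        score_df.to_csv(score_path, sep="\t")
        manifest.record("score", [score_path], seed, t0)
        results["signature_scores"] = score_df

    # ---- connectome + ligand activity --------------------------------------
    if config.lr_path and config.prior_path:
        t0 = time.time()
        lr = cio.read_lr_table(config.lr_path)
        prior = cio.read_regulatory_potential(config.prior_path)
        up = circ.upregulated_sets(dge, fdr=config.dge.fdr, lfc=config.dge.lfc_up)
        fractions = circ.sender_expression_fractions(adata, prior.index.tolist())
        tested = set(dge["gene"])
        outputs = []
        results["connectomes"], results["reports"] = {}, {}
        for trt in sorted({t for (t, _) in up}):
            conn = circ.induced_connectome(up, lr, trt)
            ligand_tables = {}
            for (t2, ct), program in up.items():
                if t2 != trt:
                    continue
                ligand_tables[ct] = circ.ligand_activity(
                    program, prior, fractions, tested_genes=tested,
                    min_sender_fraction=config.sender_fraction,
                    min_pcc=config.pcc_min,
                )
            report = circ.assemble_circuits(conn, ligand_tables, prior, up)
            edge_path = outdir / f"connectome_{trt}.tsv"
            conn.to_frame().to_csv(edge_path, sep="\t", index=False)
            gml_path = outdir / f"connectome_{trt}.graphml"
            conn.write_graphml(gml_path)
            report_path = outdir / f"circuit_report_{trt}.tsv"
            report.to_csv(report_path, sep="\t", index=False)
            outputs += [edge_path, gml_path, report_path]
            results["connectomes"][trt] = conn
            results["reports"][trt] = report
        manifest.record("circuits", outputs, config.seed, t0)

    return {"stages": manifest.stages}, results


def export_toxatlas_tables(adata, dge: pd.DataFrame, genes) -> dict:
    """Tidy per-(gene, cell type, treatment) tables for an expression browser.

    Returns ``{"expression": DataFrame, "dge": DataFrame, "unmatched": [...]}``
    where the expression table carries fraction-expressing and mean lognorm
    value per group and unknown genes are listed, never silently dropped.
    """
    known = [g for g in genes if g in set(adata.var_names)]
    unmatched = [g for g in genes if g not in set(adata.var_names)]
    expression = (
        gs.dotplot_stats(adata, known) if known else pd.DataFrame(
            columns=["cell_type", "treatment", "gene",
                     "fraction_expressing", "mean_expression"]
        )
    )
    dge_rows = dge[dge["gene"].isin(known)].copy() if len(dge) else dge
    return {"expression": expression, "dge": dge_rows, "unmatched": unmatched}
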