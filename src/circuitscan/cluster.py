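"""Consensus HVG selection, PCA/kNN embedding, Leiden clustering, marker
detection, and two-tier cell-type annotation.

The annotation strategy mirrors the whole-lung workflow: cluster the full
atlas, assign each cluster to one of four lineages by its defining gene
(epithelial Epcam, endothelial Cldn5, stromal Col1a2, immune Ptprc), then
re-run HVG selection, PCA and Leiden within each lineage and match the fine
clusters to reference marker sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.sparse as sp

from ._stats import bh_adjust, wilcoxon_rank_sum_matrix
from .simulate import LINEAGE_GENES

__all__ = [
    "HVGSelection",
    "MarkerReference",
    "select_hvgs_consensus",
    "embed_and_graph",
    "cluster_leiden",
    "rank_markers_wilcoxon",
    "annotate_types",
    "default_marker_reference",
]

log = logging.getLogger(__name__)

LINEAGE_ORDER = ("epithelial", "endothelial", "stromal", "immune")


@dataclass
class HVGSelection:
    per_sample: pd.DataFrame  # genes × samples boolean flags
    consensus: list  # genes flagged HVG in >= min_samples samples
    n_hvgs_per_sample: int


@dataclass
class MarkerReference:
    """Lineage-defining genes, fine-type marker sets, and the type→niche map."""

    lineage_genes: dict = field(default_factory=lambda: dict(LINEAGE_GENES))
    fine_markers: dict = field(default_factory=dict)  # fine type -> [genes]
    fine_lineage: dict = field(default_factory=dict)  # fine type -> lineage
    niche_map: dict = field(default_factory=dict)  # fine type -> niche


def default_marker_reference(truth) -> MarkerReference:
    """Marker reference matching the simulator's planted types."""
    fine = {
        name: [f"mk_{name}_{j}" for j in range(50) if f"mk_{name}_{j}" in set(truth.genes)]
        for name in truth.cell_types
    }
    return MarkerReference(
        fine_markers=fine,
        fine_lineage=dict(truth.lineages),
        niche_map=dict(truth.niches),
    )


def _lognorm(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("lognormalized layer required; run qc.lognormalize first")
    L = adata.layers["lognorm"]
    return L.toarray() if sp.issparse(L) else np.asarray(L)


def select_hvgs_consensus(
    adata: ad.AnnData,
    n_top: int = 2000,
    sample_key: str = "sample_id",
    min_samples: int = 2,
) -> HVGSelection:
    """Dispersion-based HVGs per sample; consensus = flagged in ≥ 2 samples.

    Each sample's top ``n_top`` genes are selected independently with the
    Seurat normalized-dispersion flavor; a gene enters the consensus list
    only if it is flagged in at least ``min_samples`` samples.
    """
    samples = adata.obs[sample_key].unique().tolist()
    if len(samples) < 2:
        raise ValueError("consensus HVG selection requires >= 2 samples")
    flags = pd.DataFrame(False, index=adata.var_names, columns=samples)
    L = _lognorm(adata)
    for s in samples:
        mask = (adata.obs[sample_key] == s).to_numpy()
        sub = ad.AnnData(X=L[mask], var=pd.DataFrame(index=adata.var_names))
        n = min(n_top, sub.n_vars - 1)
        sc.pp.highly_variable_genes(sub, flavor="seurat", n_top_genes=n)
        flags[s] = sub.var["highly_variable"].to_numpy()
    counts = flags.sum(axis=1)
    consensus = [g for g in adata.var_names if counts[g] >= min_samples]
    return HVGSelection(per_sample=flags, consensus=consensus, n_hvgs_per_sample=n_top)


def embed_and_graph(
    adata: ad.AnnData,
    hvgs: list,
    n_pcs: int = 50,
    k: int = 15,
    seed: int = 0,
):
    """PCA on scaled consensus-HVG values and a symmetric kNN graph.

    HVG lognorm values are mean-centered and unit-scaled per gene, embedded
    with PCA (n_pcs, capped at the data rank), and a k-nearest-neighbor
    graph is built on the PC coordinates. Returns ``(pcs, connectivities)``
    and stores both on ``adata`` (``.obsm['X_pca']``,
    ``.obsp['connectivities']``).
    """
    if k >= adata.n_obs:
        raise ValueError("fewer cells than requested neighbors")
    hvg_idx = adata.var_names.get_indexer(pd.Index(hvgs))
    if (hvg_idx < 0).any():
        raise ValueError("HVG list contains genes absent from the matrix")
    Z = _lognorm(adata)[:, hvg_idx].copy()
    Z -= Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z /= sd
    n_comp = int(min(n_pcs, Z.shape[0] - 1, Z.shape[1] - 1))
    if n_comp < 1:
        raise ValueError("need at least 2 cells and 2 HVGs for PCA")
    emb = ad.AnnData(X=Z)
    sc.tl.pca(emb, n_comps=n_comp, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(emb, n_neighbors=k, n_pcs=n_comp, random_state=seed)
    pcs = emb.obsm["X_pca"]
    conn = emb.obsp["connectivities"]
    adata.obsm["X_pca"] = pcs
    adata.obsp["connectivities"] = conn
    return pcs, conn


def cluster_leiden(graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Leiden community detection on a (sparse) weighted adjacency matrix.

    Uses the RB-configuration (modularity with resolution) objective;
    deterministic given ``seed``. Disconnected components always end up in
    different communities.
    """
    A = sp.csr_matrix(graph)
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    A = A.maximum(A.T)  # symmetrize
    sources, targets = A.nonzero()
    upper = sources < targets
    g = igraph.Graph(
        n=A.shape[0],
        edges=list(zip(sources[upper].tolist(), targets[upper].tolist())),
        edge_attrs={"weight": np.asarray(A[sources[upper], targets[upper]]).ravel().tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def rank_markers_wilcoxon(
    adata: ad.AnnData,
    labels,
    top_n: int = 500,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table.

    For every cluster, each gene is tested cluster-vs-rest with the
    tie-corrected normal approximation; p-values are BH-adjusted across
    genes within the cluster contrast. A gene is flagged ``is_marker`` when
    q < 0.05 AND log2FC > 0.5 (both required). Rows are ranked within each
    cluster by the test statistic.
    """
    labels = np.asarray(labels)
    L = _lognorm(adata)
    expm1 = np.expm1(L)
    frames = []
    for cl in pd.unique(labels):
        mask = labels == cl
        if mask.sum() < 2:
            log.warning("cluster %s has < 2 cells; skipped", cl)
            continue
        z, p = wilcoxon_rank_sum_matrix(L, mask)
        q = bh_adjust(p)
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        df = pd.DataFrame(
            {
                "cluster": cl,
                "gene": adata.var_names,
                "z": z,
                "log2FC": lfc,
                "p": p,
                "q": q,
            }
        )
        df["is_marker"] = (df["q"] < fdr_threshold) & (df["log2FC"] > lfc_threshold)
        df = df.sort_values("z", ascending=False)
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df.head(top_n) if top_n else df)
    return pd.concat(frames, ignore_index=True)


def _match_by_mean_expression(adata, mask, gene_sets):
    """Best-matching label = set with highest mean lognorm expression."""
    L = _lognorm(adata)[mask]
    best, best_score = None, -np.inf
    for name, genes in gene_sets.items():
        idx = adata.var_names.get_indexer(pd.Index(genes))
        idx = idx[idx >= 0]
        if idx.size == 0:
            continue
        score = float(L[:, idx].mean())
        if score > best_score:
            best, best_score = name, score
    return best


def annotate_types(
    adata: ad.AnnData,
    labels,
    reference: MarkerReference,
    n_top_hvg: int = 2000,
    resolution_fine: float = 0.8,
    k: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-tier annotation: lineage by defining gene, fine type by markers.

    Tier 1 assigns each cluster the lineage whose defining gene has the
    highest mean lognorm expression in the cluster (ties broken by the fixed
    order epithelial, endothelial, stromal, immune). Tier 2 repeats HVG
    selection, PCA/kNN and Leiden within each lineage and labels each fine
    cluster with the best-matching reference fine type of that lineage;
    niche labels follow the reference's type→niche map.

    Returns a copy of ``.obs`` with ``cluster``, ``lineage``, ``cell_type``
    and ``niche`` columns (also written back to ``adata.obs``).
    """
    labels = np.asarray(labels)
    L = _lognorm(adata)
    missing = [g for g in reference.lineage_genes.values() if g not in set(adata.var_names)]
    if missing:
        raise ValueError(f"lineage-defining genes absent from matrix: {missing}")
    lin_idx = {
        lin: adata.var_names.get_loc(g) for lin, g in reference.lineage_genes.items()
    }
    adata.obs["cluster"] = pd.Categorical(labels.astype(str))
    lineage_of_cluster = {}
    for cl in pd.unique(labels):
        mask = labels == cl
        means = {lin: float(L[mask, j].mean()) for lin, j in lin_idx.items()}
        best = max(
            LINEAGE_ORDER, key=lambda lin: (means[lin], -LINEAGE_ORDER.index(lin))
        )
        lineage_of_cluster[cl] = best
    lineage = np.array([lineage_of_cluster[cl] for cl in labels], dtype=object)
    adata.obs["lineage"] = lineage

    fine = np.array(["unassigned"] * adata.n_obs, dtype=object)
    for lin in pd.unique(lineage):
        mask = lineage == lin
        candidates = {
            t: genes
            for t, genes in reference.fine_markers.items()
            if reference.fine_lineage.get(t, lin) == lin
        }
        if not candidates:
            continue
        sub = adata[mask].copy()
        if sub.n_obs < max(k + 1, 10) or sub.obs["sample_id"].nunique() < 2:
            # too small to re-cluster: match the whole lineage block at once
            fine[mask] = _match_by_mean_expression(adata, mask, candidates)
            continue
        try:
            hv = select_hvgs_consensus(sub, n_top=n_top_hvg)
            _, conn = embed_and_graph(sub, hv.consensus, k=min(k, sub.n_obs - 1), seed=seed)
            sub_labels = cluster_leiden(conn, resolution=resolution_fine, seed=seed)
        except ValueError:
            # degenerate block (e.g. too few consensus HVGs): no re-clustering
            fine[mask] = _match_by_mean_expression(adata, mask, candidates)
            continue
        global_idx = np.flatnonzero(mask)
        for fc in pd.unique(sub_labels):
            cells = global_idx[sub_labels == fc]
            cell_mask = np.zeros(adata.n_obs, dtype=bool)
            cell_mask[cells] = True
            fine[cells] = _match_by_mean_expression(adata, cell_mask, candidates)
    adata.obs["cell_type"] = fine
    adata.obs["niche"] = [reference.niche_map.get(t, "unknown") for t in fine]
    return adata.obs.copy()
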