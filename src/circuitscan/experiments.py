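"""Self-contained calibration and recovery studies on the synthetic atlas.

Two study designs back the package's headline claims:

* :func:`null_calibration` — sham-vs-sham relabeling: no planted effects, so
  every discovery is a false positive. Checks the BH false-discovery
  fraction, the induced-connectome edge count, random-signature scores and
  the uniformity of GSEA permutation p-values under the null.
* :func:`planted_recovery` — atlases with planted sender→receiver circuits
  (default effect 2^1.5 on the NB mean, 100 cells per treatment × type
  group, 50 decoy ligand-receptor pairs), run through the full pipeline:
  clustering/annotation accuracy, planted-DE recall, connectome edge
  precision/recall, and whether planted ligands top the circuit report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import circuits as circ
from . import cluster as clu
from . import dge as dge_mod
from . import genesets as gs
from . import qc as qc_mod
from .simulate import PlantedCircuit, SimConfig, generate_atlas, make_lr_resources

__all__ = ["null_calibration", "planted_recovery", "default_planted_circuits"]


def default_planted_circuits():
    """The two reference circuits planted in recovery studies: an epithelial
    alarmin axis (AT2 Il33 → lipofibroblast Il1rl1) under CNP and a myeloid
    chemokine axis (macrophage Cxcl1 → AT2 Cxcr2) under MWCNT."""
    return (
        PlantedCircuit("CNP", "AT2", "Il33", "Lipofibroblast", "Il1rl1"),
        PlantedCircuit("MWCNT", "Alveolar_macrophage", "Cxcl1", "AT2", "Cxcr2"),
    )


def _prep(adata):
    adata = qc_mod.filter_genes(adata)
    adata = qc_mod.filter_cells(adata)
    return qc_mod.lognormalize(adata)


def null_calibration(
    n_reps: int = 20,
    n_genes: int = 2000,
    n_cells: int = 200,
    n_random_sets: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Sham-vs-sham relabeled simulations: false-positive calibration.

    One sham-only atlas per 4 reps; in each rep the sham cells of one cell
    type are randomly split into two pseudo-groups and tested exactly like
    a treatment contrast. Also scores ``n_random_sets`` random gene sets
    per-cell and runs preranked GSEA of random sets against a null log2FC
    ranking. Returns the calibration summary (rates and p-values).
    """
    rng = np.random.default_rng(seed)
    q05_fracs, edge_counts = [], []
    ranking = None
    for rep in range(n_reps):
        if rep % 4 == 0:
            config = SimConfig(
                n_cell_types=1,
                n_genes=n_genes,
                cells_per_sample_per_type=n_cells // 2,
                samples_per_treatment=2,
                treatments=("sham",),
                seed=seed + 1000 + rep,
            )
            adata, truth = generate_atlas(config)
            adata = _prep(adata)
            lr, _ = make_lr_resources(truth, n_decoy_pairs=50, seed=seed + rep)
        labels = np.where(
            rng.random(adata.n_obs) < 0.5, "sham", "shamB"
        )
        adata.obs["treatment"] = labels
        dge = dge_mod.dge_per_celltype(adata, sham_label="sham")
        q05_fracs.append(float((dge["q"] < 0.05).mean()))
        up = circ.upregulated_sets(dge)
        conn = circ.induced_connectome(up, lr, "shamB")
        edge_counts.append(len(conn.edges))
        if ranking is None:
            ranking = dge.set_index("gene")["log2FC"]

    # random-signature null: mean score across cells ~ 0
    adata.obs["treatment"] = "sham"
    universe = np.asarray(adata.var_names)
    set_means = []
    for i in range(20):
        genes = rng.choice(universe, size=30, replace=False)
        s = gs.score_gene_set(adata, list(genes), seed=seed + i)
        set_means.append(s.mean() / (s.std(ddof=1) / np.sqrt(s.size)))
    # GSEA permutation-p uniformity for random sets on a null ranking
    gsea_ps = []
    for i in range(n_random_sets):
        genes = rng.choice(universe[np.isin(universe, ranking.index)], size=15, replace=False)
        res = gs.gsea_preranked(ranking, list(genes), n_perm=n_perm, seed=seed + 5000 + i)
        gsea_ps.append(res["p"])
    from scipy.stats import kstest

    ks_p = float(kstest(gsea_ps, "uniform").pvalue)
    return {
        "q05_fraction_mean": float(np.mean(q05_fracs)),
        "q05_fractions": q05_fracs,
        "connectome_edges_mean": float(np.mean(edge_counts)),
        "signature_score_z": [float(z) for z in set_means],
        "gsea_p_ks_uniform_p": ks_p,
        "gsea_p_values": [float(p) for p in gsea_ps],
    }


def planted_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n_decoy_pairs: int = 50,
    log2_effect: float = 1.5,
    n_top_hvg: int = 300,
) -> dict:
    """Full-pipeline recovery of planted circuits over ``n_seeds`` atlases.

    Every atlas has 100 cells per (treatment, cell type) group before QC
    and the two reference circuits at ``log2_effect``. Cell types come from
    Leiden clustering plus marker-based annotation (not the planted
    labels), so the whole chain is exercised. Returns per-seed and averaged
    metrics.
    """
    aris, de_up, top5_hits, precisions, recalls = [], [], [], [], []
    for i in range(n_seeds):
        s = seed + 17 * i
        planted = tuple(
            PlantedCircuit(
                c.treatment, c.sender_type, c.ligand,
                c.receiver_type, c.receptor, log2_effect=log2_effect,
            )
            for c in default_planted_circuits()
        )
        config = SimConfig(seed=s, circuits=planted)
        adata, truth = generate_atlas(config)
        adata = _prep(adata)
        truth_labels = adata.obs["cell_type"].to_numpy().copy()
        hv = clu.select_hvgs_consensus(adata, n_top=n_top_hvg)
        clu.embed_and_graph(adata, hv.consensus, seed=s)
        labels = clu.cluster_leiden(adata.obsp["connectivities"], seed=s)
        reference = clu.default_marker_reference(truth)
        clu.annotate_types(adata, labels, reference, n_top_hvg=n_top_hvg, seed=s)
        aris.append(adjusted_rand_score(truth_labels, adata.obs["cell_type"].to_numpy()))

        dge = dge_mod.dge_per_celltype(adata)
        merged = truth.de_frame().merge(
            dge, on=["treatment", "cell_type", "gene"], how="left"
        )
        de_up.append(float((merged["direction"] == "up").mean()))

        lr, prior = make_lr_resources(truth, n_decoy_pairs=n_decoy_pairs, seed=s)
        up = circ.upregulated_sets(dge)
        fractions = circ.sender_expression_fractions(adata, prior.index.tolist())
        tested = set(dge["gene"])
        for trt in ("CNP", "MWCNT"):
            conn = circ.induced_connectome(up, lr, trt)
            found = set(conn.edges)
            planted_edges = {
                (c.sender_type, c.receiver_type)
                for c in truth.circuits
                if c.treatment == trt
            }
            precisions.append(len(found & planted_edges) / max(len(found), 1))
            recalls.append(len(found & planted_edges) / len(planted_edges))
            tables = {
                ct: circ.ligand_activity(
                    up.get((trt, ct), set()), prior, fractions, tested_genes=tested
                )
                for ct in truth.cell_types
            }
            report = circ.assemble_circuits(conn, tables, prior, up)
            top5 = set(
                map(tuple, report.head(5)[["sender", "ligand", "receiver"]].to_numpy())
            )
            planted_triples = {
                (c.sender_type, c.ligand, c.receiver_type)
                for c in truth.circuits
                if c.treatment == trt
            }
            top5_hits.append(float(planted_triples <= top5))
    return {
        "ari_mean": float(np.mean(aris)),
        "aris": [float(a) for a in aris],
        "planted_de_up_rate": float(np.mean(de_up)),
        "connectome_precision": float(np.mean(precisions)),
        "connectome_recall": float(np.mean(recalls)),
        "ligand_top5_rate": float(np.mean(top5_hits)),
    }
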