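"""Synthetic multi-sample, multi-treatment UMI atlas generator with planted truth.

The generator emulates the structure of a whole-lung nanomaterial-exposure
atlas: several instilled treatment groups plus pooled sham controls, a few
samples (mice) per group, a handful of planted cell types spanning the four
lung lineages (epithelial Epcam+, endothelial Cldn5+, stromal Col1a2+,
immune Ptprc+), mitochondrial genes for QC, and — optionally — planted
treatment-specific differential expression and sender→receiver
ligand–receptor "circuits". Counts follow a negative binomial with lognormal
per-cell size factors, the accepted noise model for UMI data.

Everything planted is returned as a :class:`PlantedTruth`, so every
downstream stage (QC, clustering, DGE, connectome, ligand activity) can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SimConfig",
    "PlantedCircuit",
    "PlantedDE",
    "PlantedTruth",
    "generate_atlas",
    "inject_doublets",
    "make_lr_resources",
    "default_type_roster",
    "LINEAGE_GENES",
    "CYTOKINES",
    "RECEPTORS",
    "MITO_GENES",
]

#: lineage-defining genes, in the fixed tie-break order used throughout
LINEAGE_GENES = {
    "epithelial": "Epcam",
    "endothelial": "Cldn5",
    "stromal": "Col1a2",
    "immune": "Ptprc",
}

#: cytokine/alarmin symbols reused for planted ligands so reports read naturally
CYTOKINES = ("Cxcl1", "Csf2", "Ccl2", "Ccl7", "Ccl11", "Ccl19", "Il33", "Il1a")

#: receptor symbols paired with the cytokines above
RECEPTORS = ("Cxcr2", "Csf2rb", "Ccr2", "Ccr1", "Ccr3", "Ccr7", "Il1rl1", "Il1r1")

#: mouse mitochondrial genes (10, "mt-" prefix) so name-based QC works unchanged
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
    "mt-Co3", "mt-Nd3", "mt-Nd4", "mt-Nd5", "mt-Cytb",
)

# (type name, lineage, niche) roster; cycled/truncated to n_cell_types
_ROSTER = (
    ("AT2", "epithelial", "alveolar_epithelium"),
    ("Lipofibroblast", "stromal", "fibroblast"),
    ("gCap_EC", "endothelial", "vascular"),
    ("Alveolar_macrophage", "immune", "myeloid"),
    ("AT1", "epithelial", "alveolar_epithelium"),
    ("Adventitial_fibroblast", "stromal", "fibroblast"),
    ("Neutrophil", "immune", "granulocyte"),
    ("Club", "epithelial", "airway_epithelium"),
    ("Vein_EC", "endothelial", "vascular"),
    ("B_cell", "immune", "lymphoid"),
)


def default_type_roster(n_cell_types: int):
    """Return ``[(name, lineage, niche), ...]`` for ``n_cell_types`` planted types."""
    roster = []
    for i in range(n_cell_types):
        if i < len(_ROSTER):
            roster.append(_ROSTER[i])
        else:
            lin = list(LINEAGE_GENES)[i % 4]
            roster.append((f"type_{i}", lin, f"niche_{i % 4}"))
    return roster


@dataclass(frozen=True)
class PlantedCircuit:
    """One planted sender→receiver communication circuit.

    Under ``treatment``, the ``ligand`` is upregulated in ``sender_type``
    and the ``receptor`` plus a downstream target program are upregulated in
    ``receiver_type``, each by ``2**log2_effect`` on the negative-binomial
    mean. ``targets`` is filled in by the generator.
    """

    treatment: str
    sender_type: str
    ligand: str
    receiver_type: str
    receptor: str
    log2_effect: float = 1.5
    n_targets: int = 15
    targets: tuple = ()


@dataclass(frozen=True)
class PlantedDE:
    treatment: str
    cell_type: str
    gene: str
    log2_effect: float


@dataclass
class PlantedTruth:
    """Ground truth of every planted effect, plus the simulated universes."""

    circuits: list
    de_genes: list
    genes: list
    cell_types: list
    lineages: dict
    niches: dict

    def de_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.treatment, d.cell_type, d.gene, d.log2_effect) for d in self.de_genes],
            columns=["treatment", "cell_type", "gene", "log2_effect"],
        )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic atlas.

    Defaults describe the study conditions the pipeline is tested under:
    four lung cell types across the four lineages, two samples per
    treatment group with 50 cells per type each (100 cells per
    treatment × type group), a ~1,500-gene universe, sham plus two
    particle treatments.
    """

    n_cell_types: int = 4
    n_genes: int = 1500
    cells_per_sample_per_type: int = 50
    samples_per_treatment: int = 2
    treatments: tuple = ("sham", "CNP", "MWCNT")
    base_mean: float = 0.5
    nb_dispersion: float = 0.4
    marker_genes_per_type: int = 10
    marker_fold: float = 8.0
    doublet_rate: float = 0.0
    mito_gene_fraction: float = 0.05
    seed: int = 0
    circuits: tuple = ()
    de_genes: tuple = ()
    size_factor_sigma: float = 0.3
    gene_mean_sigma: float = 1.0
    planted_gene_mean_fold: float = 4.0

    def validate(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1:
            raise ValueError("n_cell_types and n_genes must be >= 1")
        if self.cells_per_sample_per_type < 1 or self.samples_per_treatment < 1:
            raise ValueError("cell/sample counts must be >= 1")
        if "sham" not in self.treatments:
            raise ValueError('treatments must include "sham"')
        if not (0.0 <= self.doublet_rate < 0.5):
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if not (0.0 <= self.mito_gene_fraction < 1.0):
            raise ValueError("mito_gene_fraction must be a fraction")
        if self.base_mean <= 0 or self.nb_dispersion <= 0 or self.marker_fold <= 0:
            raise ValueError("base_mean, nb_dispersion, marker_fold must be positive")


def _gene_universe(config: SimConfig, roster):
    """Lay out the gene name vector: lineage genes, cytokines/receptors,
    per-type markers, mito block, then anonymous background genes."""
    names = list(LINEAGE_GENES.values()) + list(CYTOKINES) + list(RECEPTORS)
    for name, _, _ in roster:
        for j in range(config.marker_genes_per_type):
            names.append(f"mk_{name}_{j}")
    names.extend(MITO_GENES)
    if len(names) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for "
            f"{len(names)} structural genes; increase n_genes"
        )
    names.extend(f"g{i:05d}" for i in range(config.n_genes - len(names)))
    return names


def _validate_planted(config: SimConfig, genes, type_names):
    gene_set = set(genes)
    type_set = set(type_names)
    for c in config.circuits:
        for g in (c.ligand, c.receptor):
            if g not in gene_set:
                raise ValueError(f"planted circuit references unknown gene {g!r}")
        for t in (c.sender_type, c.receiver_type):
            if t not in type_set:
                raise ValueError(f"planted circuit references unknown cell type {t!r}")
        if c.treatment not in config.treatments:
            raise ValueError(f"planted circuit references unknown treatment {c.treatment!r}")
        if c.log2_effect == 0:
            raise ValueError("planted log2_effect must be nonzero")
    for d in config.de_genes:
        if d.gene not in gene_set:
            raise ValueError(f"planted DE references unknown gene {d.gene!r}")
        if d.cell_type not in type_set:
            raise ValueError(f"planted DE references unknown cell type {d.cell_type!r}")
        if d.treatment not in config.treatments:
            raise ValueError(f"planted DE references unknown treatment {d.treatment!r}")
        if d.log2_effect == 0:
            raise ValueError("planted log2_effect must be nonzero")


def generate_atlas(config: SimConfig):
    """Simulate a UMI atlas; returns ``(AnnData, PlantedTruth)``.

    The AnnData holds raw counts (CSR, cells × genes) with per-cell
    ``sample_id``, ``treatment`` and the true ``cell_type`` / ``niche``
    labels in ``.obs``. Identical config (including seed) gives identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roster = default_type_roster(config.n_cell_types)
    type_names = [r[0] for r in roster]
    lineages = {name: lin for name, lin, _ in roster}
    niches = {name: niche for name, _, niche in roster}
    genes = _gene_universe(config, roster)
    _validate_planted(config, genes, type_names)
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # baseline mean per gene: lognormal across genes (real transcriptomes span
    # orders of magnitude; E[baseline] = base_mean), except structural genes
    # (lineage, markers, cytokines, receptors) pinned at base_mean so planted
    # effects have predictable power. Markers and lineage genes are boosted
    # marker_fold-fold in their own types; the mito block is scaled to the
    # requested fraction of per-cell counts.
    sg = config.gene_mean_sigma
    baseline = rng.lognormal(
        mean=np.log(config.base_mean) - sg**2 / 2.0, sigma=sg, size=n_genes
    )
    n_struct = len(LINEAGE_GENES) + len(CYTOKINES) + len(RECEPTORS) + (
        config.n_cell_types * config.marker_genes_per_type
    )
    baseline[:n_struct] = config.base_mean
    # cytokines and receptors are well-expressed at baseline, like induced
    # chemokines/alarmins in inflamed lung
    for g in CYTOKINES + RECEPTORS:
        baseline[gene_index[g]] = config.base_mean * config.planted_gene_mean_fold
    base = np.tile(baseline, (config.n_cell_types, 1))
    for t_idx, (name, lin, _) in enumerate(roster):
        base[t_idx, gene_index[LINEAGE_GENES[lin]]] = config.base_mean * config.marker_fold
        for j in range(config.marker_genes_per_type):
            base[t_idx, gene_index[f"mk_{name}_{j}"]] = config.base_mean * config.marker_fold
    mito_idx = [gene_index[g] for g in MITO_GENES]
    non_mito_sum = base.sum(axis=1) - base[:, mito_idx].sum(axis=1)
    f = config.mito_gene_fraction
    mito_mean = f * non_mito_sum / ((1.0 - f) * len(MITO_GENES))
    base[:, mito_idx] = mito_mean[:, None]

    # expand planted circuits with downstream target programs drawn from the
    # adequately expressed anonymous background genes (exclusive across
    # circuits; response programs are detectable genes)
    background = [
        g
        for g in genes
        if g.startswith("g") and baseline[gene_index[g]] >= 0.5 * config.base_mean
    ]
    rng_targets = np.random.default_rng(config.seed + 1)
    order = rng_targets.permutation(len(background))
    cursor = 0
    circuits = []
    de_records = list(config.de_genes)
    for c in config.circuits:
        if c.targets:
            targets = tuple(c.targets)
        else:
            if cursor + c.n_targets > len(background):
                raise ValueError("not enough background genes for circuit targets")
            targets = tuple(background[i] for i in order[cursor : cursor + c.n_targets])
            cursor += c.n_targets
        circuits.append(replace(c, targets=targets))
        for g in targets:  # response programs are well-expressed genes
            base[:, gene_index[g]] = config.base_mean * config.planted_gene_mean_fold
        de_records.append(PlantedDE(c.treatment, c.sender_type, c.ligand, c.log2_effect))
        de_records.append(PlantedDE(c.treatment, c.receiver_type, c.receptor, c.log2_effect))
        de_records.extend(
            PlantedDE(c.treatment, c.receiver_type, g, c.log2_effect) for g in targets
        )

    # per (treatment, type) mean matrix with planted fold changes applied
    means = {}
    for trt in config.treatments:
        m = base.copy()
        for d in de_records:
            if d.treatment == trt:
                m[type_names.index(d.cell_type), gene_index[d.gene]] *= 2.0**d.log2_effect
        means[trt] = m

    # draw NB counts: gamma-poisson with dispersion θ (var = μ + θ μ²) and
    # lognormal size factors centered at E[sf] = 1
    theta = config.nb_dispersion
    sigma = config.size_factor_sigma
    blocks, obs_rows = [], []
    for trt in config.treatments:
        for s in range(config.samples_per_treatment):
            sample_id = f"{trt}_s{s + 1}"
            for t_idx, name in enumerate(type_names):
                nc = config.cells_per_sample_per_type
                mu = means[trt][t_idx]
                sf = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=nc)
                lam = rng.gamma(shape=1.0 / theta, scale=mu * theta, size=(nc, n_genes))
                counts = rng.poisson(lam * sf[:, None])
                blocks.append(sp.csr_matrix(counts))
                for _ in range(nc):
                    obs_rows.append((sample_id, trt, name, niches[name]))
    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(
        obs_rows, columns=["sample_id", "treatment", "cell_type", "niche"]
    )
    obs.index = [f"cell_{i:06d}" for i in range(len(obs))]
    obs["is_doublet"] = False
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.uns["layer"] = "raw"
    # expected per-cell total (sum of NB means) per treatment × type, the
    # Monte-Carlo oracle for library-size checks
    adata.uns["expected_total_counts"] = {
        trt: {name: float(means[trt][i].sum()) for i, name in enumerate(type_names)}
        for trt in config.treatments
    }
    truth = PlantedTruth(
        circuits=circuits,
        de_genes=de_records,
        genes=genes,
        cell_types=type_names,
        lineages=lineages,
        niches=niches,
    )
    if config.doublet_rate > 0:
        adata = inject_doublets(adata, config.doublet_rate, seed=config.seed + 2)
    return adata, truth


def inject_doublets(adata: ad.AnnData, rate: float, seed: int):
    """Append ``round(rate * n_cells)`` doublets, each the sum of two distinct
    random parent cells' count vectors (UMI counts add). Parents are recorded
    in ``.obs`` and doublets carry ``is_doublet = True``.
    """
    if not (0.0 <= rate < 0.5):
        raise ValueError("rate must be in [0, 0.5)")
    n = adata.n_obs
    n_doub = int(round(rate * n))
    if n_doub == 0:
        out = adata.copy()
        out.obs["is_doublet"] = out.obs.get("is_doublet", False)
        return out
    rng = np.random.default_rng(seed)
    parents = np.empty((n_doub, 2), dtype=int)
    for i in range(n_doub):
        parents[i] = rng.choice(n, size=2, replace=False)
    X = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    doub_X = X[parents[:, 0]] + X[parents[:, 1]]
    obs = adata.obs.copy()
    p0 = obs.iloc[parents[:, 0]]
    doub_obs = pd.DataFrame(
        {
            "sample_id": p0["sample_id"].to_numpy(),
            "treatment": p0["treatment"].to_numpy(),
            "cell_type": "doublet",
            "niche": "doublet",
            "is_doublet": True,
        },
        index=[f"doublet_{i:05d}" for i in range(n_doub)],
    )
    doub_obs["parent_a"] = adata.obs_names.to_numpy()[parents[:, 0]]
    doub_obs["parent_b"] = adata.obs_names.to_numpy()[parents[:, 1]]
    obs["parent_a"] = ""
    obs["parent_b"] = ""
    out = ad.AnnData(
        X=sp.vstack([X, doub_X]).tocsr(),
        obs=pd.concat([obs, doub_obs]),
        var=adata.var.copy(),
    )
    out.uns.update(adata.uns)
    return out


def make_lr_resources(
    truth: PlantedTruth,
    n_decoy_pairs: int = 50,
    n_decoy_ligands: int = 0,
    seed: int = 0,
    on_target_range=(0.65, 1.0),
    off_target_range=(0.0, 0.25),
):
    """Build matched ligand-receptor and regulatory-potential resources.

    Returns ``(lr_table, prior)``: a two-column DataFrame of
    (ligand, receptor) rows containing every planted pair plus
    ``n_decoy_pairs`` decoy pairs drawn from genes without planted effects,
    and a ligand × target DataFrame of regulatory potentials in [0, 1] in
    which each planted ligand carries high weight on its planted downstream
    targets and near-random low weight elsewhere. ``n_decoy_ligands`` adds
    extra prior-only ligand rows beyond those in the pair table.
    """
    if not truth.circuits and n_decoy_pairs == 0:
        raise ValueError("need planted circuits or decoy pairs")
    rng = np.random.default_rng(seed)
    planted_pairs = [(c.ligand, c.receptor) for c in truth.circuits]
    de_genes = {d.gene for d in truth.de_genes}
    pool = [
        g
        for g in truth.genes
        if g not in de_genes and not g.startswith("mt-") and g not in set(sum(map(list, planted_pairs), []))
    ]
    if 2 * (n_decoy_pairs + n_decoy_ligands) > len(pool):
        raise ValueError("decoy counts exceed available non-DE genes")
    chosen = rng.choice(len(pool), size=2 * n_decoy_pairs + n_decoy_ligands, replace=False)
    decoy_pairs = [
        (pool[chosen[2 * i]], pool[chosen[2 * i + 1]]) for i in range(n_decoy_pairs)
    ]
    extra_ligands = [pool[chosen[2 * n_decoy_pairs + i]] for i in range(n_decoy_ligands)]
    rows = list(dict.fromkeys(planted_pairs + decoy_pairs))  # dedupe, keep order
    lr_table = pd.DataFrame(rows, columns=["ligand", "receptor"])

    ligands = list(dict.fromkeys([r[0] for r in rows] + extra_ligands))
    targets = [g for g in truth.genes if not g.startswith("mt-")]
    t_index = {g: i for i, g in enumerate(targets)}
    lo, hi = off_target_range
    w = rng.uniform(lo, hi, size=(len(ligands), len(targets)))
    on_lo, on_hi = on_target_range
    for c in truth.circuits:
        li = ligands.index(c.ligand)
        for g in c.targets:
            if g in t_index:
                w[li, t_index[g]] = rng.uniform(on_lo, on_hi)
    prior = pd.DataFrame(w, index=pd.Index(ligands, name="ligand"), columns=targets)
    return lr_table, prior
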