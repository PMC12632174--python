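"""Induced connectome and NicheNet-style ligand activity.

The induced connectome is a directed cell-type communication graph built
per treatment from the differential-expression results: a (ligand, receptor)
pair from the resource table contributes an edge sender→receiver whenever
the ligand is in the sender's treatment-induced up-set and the receptor is
in the receiver's; the edge weight is the number of contributing pairs.
Autocrine self-edges are allowed.

Ligand activity follows the NicheNet idea reduced to its two printed
filters: the ligand's regulatory-potential vector over the target universe
must correlate (Pearson > 0.05) with the 0/1 membership of the receiver's
perturbed gene program, and some sender cell type must express the ligand
in at least 10% of its cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Connectome",
    "upregulated_sets",
    "induced_connectome",
    "sender_expression_fractions",
    "ligand_activity",
    "assemble_circuits",
]


@dataclass
class Connectome:
    """Directed cell-type communication graph for one treatment.

    ``edges`` maps (sender, receiver) to the list of (ligand, receptor)
    pairs shared as upregulated genes; the weight of an edge is the length
    of its pair list.
    """

    treatment: str
    edges: dict = field(default_factory=dict)

    def weight(self, sender, receiver) -> int:
        return len(self.edges.get((sender, receiver), []))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.treatment, s, r, len(pairs), ";".join(f"{l}-{rc}" for l, rc in pairs))
            for (s, r), pairs in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["treatment", "sender", "receiver", "weight", "pairs"]
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(treatment=self.treatment)
        for (s, r), pairs in self.edges.items():
            g.add_edge(s, r, weight=len(pairs), pairs=";".join(f"{l}-{rc}" for l, rc in pairs))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def upregulated_sets(
    dge: pd.DataFrame,
    fdr: float = 0.05,
    lfc: float = 0.5,
) -> dict:
    """Per (treatment, cell_type) sets of significantly upregulated genes.

    A gene qualifies when q < ``fdr`` and log2FC strictly greater than
    ``lfc`` (a gene at exactly 0.5 is excluded). Every (treatment,
    cell_type) present in the table gets a set, possibly empty.
    """
    sets = {}
    for (trt, ct), grp in dge.groupby(["treatment", "cell_type"], observed=True):
        qualifying = grp[(grp["q"] < fdr) & (grp["log2FC"] > lfc)]
        sets[(trt, ct)] = set(qualifying["gene"])
    return sets


def induced_connectome(up_sets: dict, lr: pd.DataFrame, treatment: str) -> Connectome:
    """Build the induced connectome for one treatment.

    ``up_sets`` maps (treatment, cell_type) → upregulated gene set. For every
    ordered (sender, receiver) pair of cell types and every L-R row, the pair
    joins edge sender→receiver iff ligand ∈ up_set(sender) and
    receptor ∈ up_set(receiver). Duplicate L-R rows are collapsed with a
    warning. Edges with zero qualifying pairs are not stored.
    """
    lr = lr[["ligand", "receptor"]]
    if lr.duplicated().any():
        warnings.warn("duplicate ligand-receptor rows collapsed")
        lr = lr.drop_duplicates()
    cell_types = sorted({ct for (trt, ct) in up_sets if trt == treatment})
    conn = Connectome(treatment=treatment)
    for sender in cell_types:
        up_s = up_sets.get((treatment, sender), set())
        for receiver in cell_types:
            up_r = up_sets.get((treatment, receiver), set())
            pairs = [
                (lig, rec)
                for lig, rec in lr.itertuples(index=False)
                if lig in up_s and rec in up_r
            ]
            if pairs:
                conn.edges[(sender, receiver)] = pairs
    return conn


def sender_expression_fractions(adata, ligands, cell_type_key="cell_type") -> pd.DataFrame:
    """Fraction of cells with raw count > 0 per (cell type, ligand)."""
    raw = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    idx = adata.var_names.get_indexer(pd.Index(ligands))
    known = idx >= 0
    out = {}
    for ct, grp in adata.obs.groupby(cell_type_key, observed=True):
        mask = adata.obs.index.isin(grp.index)
        frac = np.zeros(len(ligands))
        frac[known] = np.asarray((raw[mask][:, idx[known]] > 0).mean(axis=0)).ravel()
        out[ct] = frac
    return pd.DataFrame(out, index=pd.Index(ligands, name="ligand"))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a**2).sum()), np.sqrt((b**2).sum())
    if na == 0 or nb == 0:
        return np.nan
    return float((a * b).sum() / (na * nb))


def ligand_activity(
    receiver_program,
    prior: pd.DataFrame,
    sender_fractions: pd.DataFrame,
    tested_genes=None,
    min_sender_fraction: float = 0.10,
    min_pcc: float = 0.05,
) -> pd.DataFrame:
    """Score candidate ligands for one receiver's perturbed gene program.

    For each ligand (prior row), pcc is the Pearson correlation between its
    regulatory-potential vector over the prior's target universe (optionally
    intersected with ``tested_genes``) and the 0/1 membership vector of the
    receiver program. A ligand passes when pcc > ``min_pcc`` (strict) AND its
    maximum per-sender expression fraction ≥ ``min_sender_fraction``.
    Ligands with constant potential rows or degenerate (empty / all-target)
    programs get pcc = NaN and fail, with the reason recorded.
    """
    targets = prior.columns
    if tested_genes is not None:
        targets = targets[targets.isin(set(tested_genes))]
    if len(targets) == 0:
        raise ValueError("prior targets do not overlap the gene universe")
    membership = np.asarray(targets.isin(set(receiver_program)), dtype=float)
    rows = []
    for ligand in prior.index:
        vec = prior.loc[ligand, targets].to_numpy(dtype=float)
        pcc = _pearson(vec, membership)
        max_frac = (
            float(sender_fractions.loc[ligand].max())
            if ligand in sender_fractions.index
            else 0.0
        )
        reason = ""
        if np.isnan(pcc):
            reason = "degenerate correlation"
        passes = (not np.isnan(pcc)) and pcc > min_pcc and max_frac >= min_sender_fraction
        rows.append((ligand, pcc, max_frac, passes, reason))
    return pd.DataFrame(
        rows,
        columns=["ligand", "pcc", "max_sender_fraction", "passes_filters", "reason"],
    ).sort_values("pcc", ascending=False, na_position="last").reset_index(drop=True)


def assemble_circuits(
    connectome: Connectome,
    ligand_tables: dict,
    prior: pd.DataFrame,
    up_sets: dict,
) -> pd.DataFrame:
    """Join connectome edges with passing ligand activities into a report.

    ``ligand_tables`` maps receiver cell type → :func:`ligand_activity`
    output for that receiver's program. Each (sender, ligand, receiver,
    receptor) supported by both a connectome edge and a passing ligand row
    becomes a report row carrying the edge weight and the ligand's pcc;
    rows are ranked by (pcc, weight) descending. Receiver response genes are
    the receiver's up-set members among the ligand's above-median prior
    targets.
    """
    trt = connectome.treatment
    rows = []
    for (sender, receiver), pairs in connectome.edges.items():
        table = ligand_tables.get(receiver)
        if table is None:
            continue
        passing = table[table["passes_filters"]].set_index("ligand")
        for ligand, receptor in pairs:
            if ligand not in passing.index:
                continue
            pcc = float(passing.loc[ligand, "pcc"])
            response = ""
            if ligand in prior.index:
                lig_w = prior.loc[ligand]
                top_targets = set(lig_w[lig_w > lig_w.median()].index)
                response_genes = sorted(
                    up_sets.get((trt, receiver), set()) & top_targets
                )
                response = ";".join(response_genes)
            rows.append(
                (trt, sender, ligand, receiver, receptor,
                 connectome.weight(sender, receiver), pcc, response)
            )
    report = pd.DataFrame(
        rows,
        columns=["treatment", "sender", "ligand", "receiver", "receptor",
                 "connectome_weight", "ligand_pcc", "response_genes"],
    )
    return report.sort_values(
        ["ligand_pcc", "connectome_weight"], ascending=False
    ).reset_index(drop=True)
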