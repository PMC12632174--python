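"""Readers and writers for the pipeline's on-disk formats.

Counts travel as Matrix Market triplets with sidecar gene/barcode TSVs
(10x-style), metadata and tables as TSV, planted truth as JSON, gene sets
as GMT, and connectomes as GraphML / edge-list TSV. Every writer has a
matching reader.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import PlantedCircuit, PlantedDE, PlantedTruth

__all__ = [
    "write_counts",
    "read_counts",
    "write_meta",
    "read_meta",
    "write_truth",
    "read_truth",
    "read_gmt",
    "write_gmt",
    "read_lr_table",
    "write_lr_table",
    "read_regulatory_potential",
    "write_regulatory_potential",
]


def write_counts(adata: ad.AnnData, outdir) -> None:
    """Write counts as matrix.mtx + genes.tsv + barcodes.tsv (+ meta.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.tocoo())
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    if len(adata.obs.columns):
        write_meta(adata.obs, outdir / "meta.tsv")


def read_counts(indir) -> ad.AnnData:
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    meta_path = indir / "meta.tsv"
    if meta_path.exists():
        obs = read_meta(meta_path).loc[barcodes]
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["layer"] = "raw"
    return adata


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=True, index_label="barcode")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "circuits": [dataclasses.asdict(c) for c in truth.circuits],
        "de_genes": [dataclasses.asdict(d) for d in truth.de_genes],
        "genes": list(truth.genes),
        "cell_types": list(truth.cell_types),
        "lineages": dict(truth.lineages),
        "niches": dict(truth.niches),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        circuits=[
            PlantedCircuit(**{**c, "targets": tuple(c["targets"])})
            for c in payload["circuits"]
        ],
        de_genes=[PlantedDE(**d) for d in payload["de_genes"]],
        genes=payload["genes"],
        cell_types=payload["cell_types"],
        lineages=payload["lineages"],
        niches=payload["niches"],
    )


def read_gmt(path) -> dict:
    """Parse a GMT file into ``{set_name: [genes]}`` (description column dropped)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict, path) -> None:
    lines = ["\t".join([name, "na", *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["ligand", "receptor"]:
        raise ValueError("L-R table must have columns 'ligand' and 'receptor'")
    if df.duplicated(["ligand", "receptor"]).any():
        raise ValueError("duplicate (ligand, receptor) rows")
    if df[["ligand", "receptor"]].isna().any().any():
        raise ValueError("empty entries in L-R table")
    return df[["ligand", "receptor"]].astype(str)


def write_lr_table(lr: pd.DataFrame, path) -> None:
    lr[["ligand", "receptor"]].to_csv(path, sep="\t", index=False)


def read_regulatory_potential(path) -> pd.DataFrame:
    prior = pd.read_csv(path, sep="\t", index_col=0)
    vals = prior.to_numpy(dtype=float)
    if not np.isfinite(vals).all() or vals.min() < 0 or vals.max() > 1:
        raise ValueError("regulatory potentials must be finite and within [0, 1]")
    if prior.index.duplicated().any() or prior.columns.duplicated().any():
        raise ValueError("duplicate ligand or target names")
    return prior


def write_regulatory_potential(prior: pd.DataFrame, path) -> None:
    prior.to_csv(path, sep="\t", index_label="ligand")
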