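"""Per-cell-type treatment-vs-sham differential expression.

Each non-sham treatment is compared to the pooled sham cells of the same
cell type with Welch's unequal-variance t test on log-normalized values.
Only genes expressed (count > 0) in at least 10 cells of the two groups
combined are tested; BH adjustment is applied within each
(cell type, treatment) contrast; a gene is called up (down) when
q < 0.05 and log2FC > 0.5 (< −0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._stats import bh_adjust, welch_test, welch_test_matrix

__all__ = [
    "DGEThresholds",
    "welch_test",
    "dge_per_celltype",
    "effect_size_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DGEThresholds:
    min_cells_expressing: int = 10
    lfc_up: float = 0.5
    lfc_down: float = -0.5
    fdr: float = 0.05
    expressing_per_group: bool = False  # True: >= min expressing cells in EACH group

    def __post_init__(self):
        if not (self.lfc_up > 0 > self.lfc_down):
            raise ValueError("need lfc_up > 0 > lfc_down")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")


def dge_per_celltype(
    adata: ad.AnnData,
    thresholds: DGEThresholds = DGEThresholds(),
    cell_type_key: str = "cell_type",
    treatment_key: str = "treatment",
    sham_label: str = "sham",
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Welch DGE of every (cell type, treatment-vs-sham) contrast.

    Returns a long-format table with one row per tested gene per contrast:
    group means (on the de-logged scale), log2FC, Welch t / df / p, BH q
    within the contrast, the number of expressing cells, and a direction
    call in {up, down, ns}. Cell types with fewer than ``min_group_size``
    cells in either group are skipped with a log message.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("lognormalized layer required")
    L = np.asarray(adata.layers["lognorm"])
    raw = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    expressed = (raw > 0).astype(np.int64)
    obs = adata.obs
    treatments = [t for t in obs[treatment_key].unique() if t != sham_label]
    if not treatments:
        raise ValueError("no non-sham treatment present")
    frames = []
    for ct in obs[cell_type_key].unique():
        sham_mask = ((obs[cell_type_key] == ct) & (obs[treatment_key] == sham_label)).to_numpy()
        for trt in treatments:
            trt_mask = ((obs[cell_type_key] == ct) & (obs[treatment_key] == trt)).to_numpy()
            if sham_mask.sum() < min_group_size or trt_mask.sum() < min_group_size:
                log.info("skipping %s / %s: fewer than %d cells", ct, trt, min_group_size)
                continue
            n_expr_trt = np.asarray(expressed[trt_mask].sum(axis=0)).ravel()
            n_expr_sham = np.asarray(expressed[sham_mask].sum(axis=0)).ravel()
            if thresholds.expressing_per_group:
                testable = (n_expr_trt >= thresholds.min_cells_expressing) & (
                    n_expr_sham >= thresholds.min_cells_expressing
                )
            else:
                testable = (n_expr_trt + n_expr_sham) >= thresholds.min_cells_expressing
            idx = np.flatnonzero(testable)
            if idx.size == 0:
                continue
            x = L[trt_mask][:, idx].T  # genes × cells
            y = L[sham_mask][:, idx].T
            t, df, p = welch_test_matrix(x, y)
            q = bh_adjust(p)
            mean_t = np.expm1(x).mean(axis=1)
            mean_s = np.expm1(y).mean(axis=1)
            lfc = np.log2((mean_t + 1e-9) / (mean_s + 1e-9))
            direction = np.where(
                (q < thresholds.fdr) & (lfc > thresholds.lfc_up),
                "up",
                np.where((q < thresholds.fdr) & (lfc < thresholds.lfc_down), "down", "ns"),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "cell_type": ct,
                        "treatment": trt,
                        "gene": adata.var_names[idx],
                        "mean_treat": mean_t,
                        "mean_sham": mean_s,
                        "log2FC": lfc,
                        "t_statistic": t,
                        "df_welch": df,
                        "p": p,
                        "q": q,
                        "n_cells_expressing": (n_expr_trt + n_expr_sham)[idx],
                        "direction": direction,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cell_type", "treatment", "gene", "mean_treat", "mean_sham",
                "log2FC", "t_statistic", "df_welch", "p", "q",
                "n_cells_expressing", "direction",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def effect_size_summary(dge: pd.DataFrame) -> pd.DataFrame:
    """Count up/down-regulated genes per (cell type, treatment).

    The numeric substrate of the per-condition effect-size heatmap: a table
    with MultiIndex columns (treatment) × rows (cell type) holding
    ``n_up`` and ``n_down``.
    """
    if dge.empty:
        return pd.DataFrame(columns=["cell_type", "treatment", "n_up", "n_down"])
    out = (
        dge.groupby(["cell_type", "treatment"], observed=True)["direction"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .rename(columns={"up": "n_up", "down": "n_down"})
        .reset_index()
    )
    out.columns.name = None
    return out
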