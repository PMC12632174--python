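"""Quality control and normalization of raw UMI count matrices.

The QC cascade: drop genes with total count < 1 or expressed in fewer than
5 cells; drop cells with ≥ 10% mitochondrial counts, fewer than 300 detected
genes or fewer than 500 total counts; optionally score and remove doublets
with a simulated-doublet nearest-neighbor classifier; finally depth-normalize
to 10,000 counts per cell and log1p-transform. Gene filtering precedes cell
filtering, and filtering never alters retained count values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "QCThresholds",
    "compute_cell_metrics",
    "filter_genes",
    "filter_cells",
    "detect_doublets",
    "auto_doublet_threshold",
    "lognormalize",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs of the QC cascade (defaults are the reference values).

    ``min_gene_count``/``min_cells_per_gene`` act on genes; the mito, gene-
    and count-per-cell limits act on cells (mito fraction ≥ max is removed,
    genes/counts strictly below their minima are removed, so a cell at
    exactly 300 genes and 500 counts survives).
    """

    min_gene_count: int = 1
    min_cells_per_gene: int = 5
    max_mito_fraction: float = 0.10
    min_genes_per_cell: int = 300
    min_counts_per_cell: int = 500
    doublet_score_threshold: float | str = "auto"
    mito_prefix: str = "mt-"
    mito_genes: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")
        if min(self.min_gene_count, self.min_cells_per_gene,
               self.min_genes_per_cell, self.min_counts_per_cell) < 0:
            raise ValueError("count thresholds must be >= 0")


def _raw(adata: ad.AnnData) -> sp.csr_matrix:
    if adata.uns.get("layer", "raw") != "raw":
        raise ValueError("QC operates on the raw count layer")
    return adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)


def _mito_mask(adata: ad.AnnData, thresholds: QCThresholds) -> np.ndarray:
    if thresholds.mito_genes:
        return adata.var_names.isin(thresholds.mito_genes)
    return adata.var_names.str.lower().str.startswith(thresholds.mito_prefix.lower())


def compute_cell_metrics(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()):
    """Annotate ``.obs`` with total_counts, n_genes_detected and mito_fraction.

    Mitochondrial genes are found by case-insensitive name prefix (default
    "mt-") or an explicit override list; if none are present a warning is
    issued and mito_fraction is 0 for every cell.
    """
    X = _raw(adata)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito = _mito_mask(adata, thresholds)
    if mito.sum() == 0:
        warnings.warn("no mitochondrial genes found; mito_fraction set to 0")
        mito_frac = np.zeros(adata.n_obs)
    else:
        mito_counts = np.asarray(X[:, np.flatnonzero(mito)].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
    adata.obs["total_counts"] = total
    adata.obs["n_genes_detected"] = n_genes
    adata.obs["mito_fraction"] = mito_frac
    return adata


def filter_genes(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()) -> ad.AnnData:
    """Keep genes with total count ≥ min_gene_count and expressed (count > 0)
    in at least ``min_cells_per_gene`` cells; gene order is preserved."""
    X = _raw(adata)
    total = np.asarray(X.sum(axis=0)).ravel()
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = (total >= thresholds.min_gene_count) & (n_cells >= thresholds.min_cells_per_gene)
    if keep.sum() == 0:
        raise ValueError("gene filtering removed every gene; degenerate input")
    return adata[:, keep].copy()


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()) -> ad.AnnData:
    """Remove cells with mito_fraction ≥ max, n_genes < min or counts < min.

    Metrics are (re)computed on the current matrix so the call is
    self-contained; metadata rows stay in sync because they live in ``.obs``.
    """
    compute_cell_metrics(adata, thresholds)
    obs = adata.obs
    keep = (
        (obs["mito_fraction"] < thresholds.max_mito_fraction)
        & (obs["n_genes_detected"] >= thresholds.min_genes_per_cell)
        & (obs["total_counts"] >= thresholds.min_counts_per_cell)
    ).to_numpy()
    if keep.sum() == 0:
        raise ValueError("cell filtering removed every cell; degenerate input")
    adata.obs["qc_pass"] = keep
    return adata[keep].copy()


def _lognorm_dense(X: sp.csr_matrix, target_sum: float = 1e4) -> np.ndarray:
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ValueError("zero-total-count cell encountered")
    Y = X.multiply(target_sum / total[:, None]).toarray()
    return np.log1p(Y)


def detect_doublets(
    adata: ad.AnnData,
    n_sim_doublets: int | None = None,
    k: int | None = None,
    seed: int = 0,
    n_pcs: int = 30,
):
    """Simulated-doublet nearest-neighbor scoring (Scrublet-style).

    Synthetic doublets are made by summing ``n_sim_doublets`` random pairs of
    observed cells (default: one per observed cell). Observed and synthetic
    cells are pooled, depth-normalized, log1p-transformed and embedded with
    PCA; each observed cell's score is the fraction of its k nearest pooled
    neighbors that are synthetic, converted to a doublet likelihood by
    correcting for the simulation ratio r = n_sim / n_obs:

        score = (q / r) / (q / r + 1 - q),   q = k_sim / k

    Scores are in [0, 1] and stored in ``.obs['doublet_score']``; synthetic-
    doublet scores are returned as well for thresholding.
    """
    X = _raw(adata)
    n = adata.n_obs
    if n_sim_doublets is None:
        n_sim_doublets = n
    if k is None:
        k = max(3, int(round(0.5 * np.sqrt(n + n_sim_doublets))))
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    rng = np.random.default_rng(seed)
    pa = rng.integers(0, n, size=n_sim_doublets)
    pb = (pa + 1 + rng.integers(0, n - 1, size=n_sim_doublets)) % n
    sim = X[pa] + X[pb]
    pooled = sp.vstack([X, sim]).tocsr()
    Z = _lognorm_dense(pooled)
    Z -= Z.mean(axis=0)
    n_comp = min(n_pcs, Z.shape[0] - 1, Z.shape[1])
    pcs = PCA(n_components=n_comp, random_state=seed, svd_solver="randomized").fit_transform(Z)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    idx = idx[:, 1:]  # drop self
    is_sim = idx >= n
    q = is_sim.mean(axis=1)
    r = n_sim_doublets / n
    with np.errstate(divide="ignore", invalid="ignore"):
        score = (q / r) / (q / r + 1.0 - q)
    score = np.nan_to_num(np.clip(score, 0.0, 1.0))
    adata.obs["doublet_score"] = score[:n]
    return score[:n], score[n:]


def auto_doublet_threshold(sim_scores: np.ndarray, sim_recall: float = 0.75) -> float:
    """Threshold from the simulated-doublet score distribution.

    If the (smoothed) histogram of simulated-doublet scores is bimodal —
    an embedded/homotypic mode and a neotypic mode — the threshold is the
    minimum-density valley between the two modes. Otherwise the threshold
    is the score quantile retaining ``sim_recall`` of the simulated
    doublets, i.e. the operating point is chosen by simulated-doublet
    recall (simulated scores estimate the score distribution of true
    doublets).
    """
    hist, edges = np.histogram(sim_scores, bins=20, range=(0.0, 1.0))
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]
        and smooth[i] >= 0.05 * smooth.max()
    ]
    if len(peaks) >= 2 and peaks[-1] > peaks[0] + 2:
        lo, hi = peaks[0], peaks[-1]
        valley = lo + 1 + int(np.argmin(smooth[lo + 1 : hi]))
        if smooth[valley] < 0.5 * min(smooth[lo], smooth[hi]):
            return float(centers[valley])
    return float(np.quantile(sim_scores, 1.0 - sim_recall))


def lognormalize(adata: ad.AnnData, target_sum: float | None = 1e4) -> ad.AnnData:
    """Depth-normalize to ``target_sum`` counts per cell (CP10K) and log1p.

    The transformed values go to ``.layers['lognorm']``; raw counts stay in
    ``.X``. ``target_sum=None`` applies log1p to raw counts with no depth
    normalization (the literal reading of a bare log transform).
    """
    X = _raw(adata)
    if target_sum is None:
        Y = X.copy().astype(float)
        Y.data = np.log1p(Y.data)
        adata.layers["lognorm"] = Y.toarray()
    else:
        adata.layers["lognorm"] = _lognorm_dense(X, target_sum)
    adata.uns["lognorm_target_sum"] = target_sum
    return adata
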