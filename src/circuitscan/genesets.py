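"""Gene-set scoring: per-cell signature scores, GSVA, and preranked GSEA.

Three complementary views of pathway activity:

* :func:`score_gene_set` — per-cell mean expression of a set minus an
  expression-matched control pool (DAMP / hallmark signature scores);
* :func:`gsva_scores` — per-sample rank-based enrichment via the
  kernel-ECDF / random-walk recipe;
* :func:`gsea_preranked` — weighted Kolmogorov–Smirnov enrichment of a set
  in a log2FC-ranked gene list, with gene-label permutation p-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from ._stats import bh_adjust

__all__ = [
    "score_gene_set",
    "gsva_scores",
    "gsea_preranked",
    "gsea_collection",
    "dotplot_stats",
]


def _lognorm(adata):
    if "lognorm" not in adata.layers:
        raise ValueError("lognormalized layer required")
    L = adata.layers["lognorm"]
    return L.toarray() if sp.issparse(L) else np.asarray(L)


def score_gene_set(
    adata,
    gene_set,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Signature score: set mean minus expression-matched control-pool mean.

    Genes are binned by average expression into ``n_bins`` rank bins. For
    each bin touched by the set, ``ctrl_size`` control genes per set gene in
    the bin are sampled from the bin's non-set genes; a bin whose genes all
    belong to the set contributes the whole bin (so a set equal to the full
    universe scores exactly 0). Per cell:

        score = mean(lognorm over set) − mean(lognorm over control pool)

    Deterministic given ``seed``. Stored in ``.obs`` by the caller if wanted.
    """
    L = _lognorm(adata)
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = np.array([var_index[g] for g in gene_set if g in var_index])
    if set_idx.size == 0:
        raise ValueError("gene set has empty intersection with the gene universe")
    rng = np.random.default_rng(seed)
    avg = L.mean(axis=0)
    order = rankdata(avg, method="ordinal") - 1
    bins = (order * n_bins // len(avg)).astype(int)
    in_set = np.zeros(L.shape[1], dtype=bool)
    in_set[set_idx] = True
    ctrl = []
    for b in np.unique(bins[set_idx]):
        bin_genes = np.flatnonzero(bins == b)
        candidates = bin_genes[~in_set[bin_genes]]
        n_set_here = int(in_set[bin_genes].sum())
        if candidates.size == 0:
            ctrl.append(bin_genes)
        else:
            take = min(ctrl_size * n_set_here, candidates.size)
            ctrl.append(rng.choice(candidates, size=take, replace=False))
    ctrl_idx = np.unique(np.concatenate(ctrl))
    return L[:, set_idx].mean(axis=1) - L[:, ctrl_idx].mean(axis=1)


def gsva_scores(
    expr: pd.DataFrame,
    sets: dict,
    tau: float = 1.0,
    max_diff: bool = True,
) -> pd.DataFrame:
    """GSVA: per-sample gene-set variation scores on a genes × samples matrix.

    Steps (Gaussian-kernel mode for continuous/log data):

    1. per gene, a kernel-smoothed ECDF across samples with bandwidth
       sd/4 gives z_ij = mean_k Φ((x_ij − x_ik) / h_i);
    2. per sample, genes are ranked by decreasing z and converted to the
       symmetric rank statistic |p/2 − r|;
    3. a weighted random walk down the ranked list (hit steps ∝ stat^tau,
       miss steps uniform) yields, per set and sample, the score
       max positive deviation + max negative deviation ("maxdiff";
       ``max_diff=False`` returns the single largest-magnitude deviation).

    Returns a sets × samples DataFrame.
    """
    if expr.shape[1] < 2:
        raise ValueError("GSVA is relative; needs >= 2 samples")
    X = expr.to_numpy(dtype=float)
    p, n = X.shape
    sd = X.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1e-8)
    # z_ij = mean over k of Phi((x_ij - x_ik) / h_i)
    z = norm.cdf((X[:, :, None] - X[:, None, :]) / h[:, None, None]).mean(axis=2)
    # per-sample dense ranks: r=1 for the largest z
    ranks = np.empty_like(z)
    for j in range(n):
        ranks[:, j] = rankdata(-z[:, j], method="ordinal")
    stat = np.abs(p / 2.0 - ranks)
    out = {}
    for name, genes in sets.items():
        hit = expr.index.isin(genes)
        if hit.sum() == 0:
            raise ValueError(f"gene set {name!r} does not intersect the matrix")
        scores = np.empty(n)
        n_miss = p - hit.sum()
        for j in range(n):
            order = np.argsort(ranks[:, j], kind="stable")
            hits = hit[order]
            w = stat[order, j] ** tau
            denom = w[hits].sum()
            step = np.where(hits, w / (denom if denom > 0 else 1.0), -1.0 / n_miss)
            walk = np.cumsum(step)
            mx, mn = walk.max(), walk.min()
            if max_diff:
                scores[j] = max(mx, 0.0) + min(mn, 0.0)
            else:
                scores[j] = mx if abs(mx) >= abs(mn) else mn
        out[name] = scores
    return pd.DataFrame(out, index=expr.columns).T


def _es_from_positions(pos, w, n_genes):
    """Enrichment-score extrema from sorted hit positions.

    ``pos``: (B, m) sorted 0-based positions of the hits in the ranked list;
    ``w``: matching hit weights, normalized to sum 1 per row. Misses step
    down by 1/(N−m). Returns the signed ES (largest-magnitude deviation),
    plus the max and min deviations.
    """
    B, m = pos.shape
    miss = 1.0 / (n_genes - m)
    cum = np.cumsum(w, axis=1)
    i = np.arange(m)[None, :]
    dev_after = cum - (pos - i) * miss  # just after each hit
    dev_before = cum - w - (pos - i) * miss  # just before each hit
    mx = dev_after.max(axis=1)
    mn = np.minimum(dev_before.min(axis=1), 0.0)
    es = np.where(np.abs(mx) >= np.abs(mn), mx, mn)
    return es, mx, mn


def gsea_preranked(
    ranking: pd.Series,
    gene_set,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Weighted-KS enrichment of a gene set in a ranked list.

    ``ranking`` maps genes to a real-valued statistic (log2FC); genes are
    sorted by decreasing value. Hits step the running sum up by
    |stat|^weight_p (normalized), misses step down uniformly; the ES is the
    largest-magnitude running-sum deviation. The p-value permutes gene
    labels ``n_perm`` times and compares same-sign permutation ES
    magnitudes; NES = ES / mean |permutation ES of the same sign|.

    Returns a dict with keys ``es``, ``nes``, ``p``, ``n_hits``.
    """
    if ranking.isna().any():
        raise ValueError("ranking contains NaN")
    genes = ranking.sort_values(ascending=False, kind="stable")
    hit_set = set(gene_set) & set(genes.index)
    m = len(hit_set)
    N = len(genes)
    if m < 2:
        raise ValueError("gene set must have >= 2 genes in the ranking")
    if m > N // 2:
        raise ValueError("gene set larger than half the ranked universe")
    vals = np.abs(genes.to_numpy(dtype=float)) ** weight_p
    hit_mask = genes.index.isin(hit_set)
    pos = np.flatnonzero(hit_mask)
    w = vals[pos]
    wsum = w.sum()
    w = w / wsum if wsum > 0 else np.full(m, 1.0 / m)
    es, _, _ = _es_from_positions(pos[None, :], w[None, :], N)
    es = float(es[0])

    rng = np.random.default_rng(seed)
    perm_pos = np.argsort(rng.random((n_perm, N)), axis=1)[:, :m]
    perm_pos.sort(axis=1)
    pw = vals[perm_pos]
    pw_sum = pw.sum(axis=1, keepdims=True)
    pw = np.where(pw_sum > 0, pw / np.where(pw_sum == 0, 1, pw_sum), 1.0 / m)
    perm_es, _, _ = _es_from_positions(perm_pos, pw, N)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    p = (1 + int((np.abs(perm_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    mean_mag = np.abs(perm_es[same_sign]).mean() if n_same else np.nan
    nes = es / mean_mag if n_same and mean_mag > 0 else np.nan
    return {"es": es, "nes": nes, "p": p, "n_hits": m}


def gsea_collection(
    ranking: pd.Series,
    sets: dict,
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`gsea_preranked` over a collection and BH-adjust within it."""
    rows = []
    for i, (name, genes) in enumerate(sets.items()):
        res = gsea_preranked(ranking, genes, weight_p, n_perm, seed=seed + i)
        rows.append({"gene_set": name, "ES": res["es"], "NES": res["nes"],
                     "p": res["p"], "n_hits": res["n_hits"]})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def dotplot_stats(
    adata,
    genes,
    group_keys=("cell_type", "treatment"),
) -> pd.DataFrame:
    """Fraction of expressing cells and mean lognorm value per group per gene.

    The numeric substrate of cytokine dot/matrix plots. Unknown gene names
    raise with the full list of offenders.
    """
    unknown = [g for g in genes if g not in set(adata.var_names)]
    if unknown:
        raise KeyError(f"genes not in universe: {unknown}")
    L = _lognorm(adata)
    raw = adata.X.tocsr() if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    idx = adata.var_names.get_indexer(pd.Index(genes))
    rows = []
    for keys, grp in adata.obs.groupby(list(group_keys), observed=True):
        mask = adata.obs.index.isin(grp.index)
        sub_raw = raw[mask][:, idx]
        frac = np.asarray((sub_raw > 0).mean(axis=0)).ravel()
        mean = L[mask][:, idx].mean(axis=0)
        for g, f, m in zip(genes, frac, mean):
            rows.append((*keys, g, float(f), float(m)))
    return pd.DataFrame(
        rows, columns=[*group_keys, "gene", "fraction_expressing", "mean_expression"]
    )
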