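"""Shared statistical primitives: Welch's t, Wilcoxon rank-sum, BH FDR, log2FC.

All group comparisons in the pipeline reduce to these. The Welch test is
implemented from the textbook formulas (vectorized over genes); the Wilcoxon
rank-sum uses the normal approximation with tie correction when vectorized,
and scipy's exact method for single small-sample contrasts.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_test",
    "welch_test_matrix",
    "wilcoxon_rank_sum",
    "wilcoxon_rank_sum_matrix",
    "bh_adjust",
    "log2_fold_change",
]


def welch_test(x, y):
    """Welch's unequal-variance t test between two samples.

    Returns ``(t, df, p)`` with t = (x̄−ȳ)/sqrt(s²ₓ/nₓ + s²ᵧ/nᵧ), the
    Welch–Satterthwaite degrees of freedom, and a two-sided p-value from the
    t distribution. If both sample variances are zero the comparison is
    degenerate: p = 1 when the means are equal, otherwise t = ±inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_test requires at least 2 observations per group")
    t, df, p = welch_test_matrix(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def welch_test_matrix(x, y):
    """Vectorized Welch test: rows are variables, columns observations.

    Zero-variance rows (both groups constant) get p = 1 if the means agree
    and p = 0 with t = ±inf otherwise; df is set to nₓ+nᵧ−2 there so the
    output never contains NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[1], y.shape[1]
    mx = x.mean(axis=1)
    my = y.mean(axis=1)
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
    df = np.where(degenerate, nx + ny - 2, df)
    t = np.where(degenerate, np.where(mx == my, 0.0, np.inf * np.sign(mx - my)), t)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(degenerate & (mx == my), 1.0, p)
    p = np.where(degenerate & (mx != my), 0.0, p)
    return t, df, np.clip(p, 0.0, 1.0)


def wilcoxon_rank_sum(x, y, method: str = "auto"):
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for one gene.

    ``method`` is passed to :func:`scipy.stats.mannwhitneyu`: "auto" uses the
    exact null distribution for small tie-free samples and the tie-corrected
    normal approximation otherwise.
    """
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum_matrix(values, in_group):
    """Tie-corrected normal-approximation rank-sum test, vectorized over genes.

    Parameters
    ----------
    values
        dense (cells × genes) matrix.
    in_group
        boolean mask of the foreground cells; the complement is background.

    Returns ``(z, p)`` arrays of length n_genes. Continuity correction is not
    applied, matching the common scRNA-seq marker-test convention.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(values, axis=0)
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        tie_term[j] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu) / np.sqrt(sigma2)
    z = np.where(sigma2 == 0, 0.0, z)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, np.clip(p, 0.0, 1.0)


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(lognorm_a, lognorm_b, pseudocount: float = 1e-9):
    """log2 fold change between groups of log1p-normalized expression values.

    Group means are taken on the de-logged scale, expm1(mean is NOT delogged
    per cell; the convention is mean of expm1 values), i.e.
    log2((mean(expm1 a) + eps) / (mean(expm1 b) + eps)), matching common
    single-cell marker reporting.
    """
    a = np.expm1(np.asarray(lognorm_a, dtype=float)).mean(axis=-1)
    b = np.expm1(np.asarray(lognorm_b, dtype=float)).mean(axis=-1)
    return np.log2((a + pseudocount) / (b + pseudocount))
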