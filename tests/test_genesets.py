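"""Signature scoring, GSVA, preranked GSEA, and dot-plot statistics."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, norm

from circuitscan import genesets as gs


def _adata_lognorm(L, genes=None, obs=None):
    L = np.asarray(L, dtype=float)
    genes = genes or [f"g{i}" for i in range(L.shape[1])]
    a = ad.AnnData(
        X=sp.csr_matrix(np.round(np.expm1(L), 6)),
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(L.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    a.layers["lognorm"] = L
    a.uns["layer"] = "raw"
    return a


class TestScoreGeneSet:
    def test_full_universe_scores_exactly_zero(self, rng):
        a = _adata_lognorm(rng.gamma(2.0, 0.5, size=(30, 40)))
        s = gs.score_gene_set(a, list(a.var_names), seed=0)
        assert np.all(s == 0.0)

    def test_location_invariance(self, rng):
        L = rng.gamma(2.0, 0.5, size=(30, 60))
        a1 = _adata_lognorm(L)
        a2 = _adata_lognorm(L + 1.7)
        genes = [f"g{i}" for i in range(0, 12)]
        s1 = gs.score_gene_set(a1, genes, seed=4)
        s2 = gs.score_gene_set(a2, genes, seed=4)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_random_set_scores_center_on_zero(self, sham_atlas, rng):
        adata, _ = sham_atlas
        zs = []
        for i in range(10):
            genes = list(rng.choice(adata.var_names, size=30, replace=False))
            s = gs.score_gene_set(adata, genes, seed=i)
            zs.append(s.mean() / (s.std(ddof=1) / np.sqrt(s.size)))
        assert abs(np.mean(zs)) <= 3.0

    def test_planted_program_elevates_score_in_treated_cells(self, planted_atlas):
        adata, truth = planted_atlas
        circuit = truth.circuits[0]  # CNP: receiver Lipofibroblast
        s = gs.score_gene_set(adata, list(circuit.targets), seed=0)
        obs = adata.obs
        rec = obs["true_cell_type"] == circuit.receiver_type
        treated = s[(rec & (obs["treatment"] == circuit.treatment)).to_numpy()]
        sham = s[(rec & (obs["treatment"] == "sham")).to_numpy()]
        assert len(treated) >= 80 and len(sham) >= 80
        assert treated.mean() > sham.mean()
        assert mannwhitneyu(treated, sham, alternative="greater").pvalue < 0.01

    def test_empty_intersection_rejected(self, rng):
        a = _adata_lognorm(rng.gamma(2.0, 0.5, size=(10, 20)))
        with pytest.raises(ValueError, match="intersection"):
            gs.score_gene_set(a, ["nope"], seed=0)


def _gsva_by_hand(expr, gene_set, tau=1.0):
    """Straight-line re-derivation: kernel ECDF, ranks, random walk."""
    X = expr.to_numpy(dtype=float)
    p, n = X.shape
    z = np.zeros((p, n))
    for i in range(p):
        sd = np.std(X[i], ddof=1)
        h = sd / 4.0 if sd > 0 else 1e-8
        for j in range(n):
            z[i, j] = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(n)])
    scores = np.zeros(n)
    for j in range(n):
        order = sorted(range(p), key=lambda i: -z[i, j])
        rank = {g: r + 1 for r, g in enumerate(order)}
        stat = {i: abs(p / 2.0 - rank[i]) for i in range(p)}
        hits = [i for i in range(p) if expr.index[i] in gene_set]
        denom = sum(stat[i] ** tau for i in hits)
        walk, v, mx, mn = 0.0, 0.0, -np.inf, np.inf
        for i in order:
            if expr.index[i] in gene_set:
                v += stat[i] ** tau / denom
            else:
                v -= 1.0 / (p - len(hits))
            mx, mn = max(mx, v), min(mn, v)
        scores[j] = max(mx, 0.0) + min(mn, 0.0)
    return scores


class TestGSVA:
    def test_identical_sample_columns_get_identical_scores(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(25, 4)),
            index=[f"g{i}" for i in range(25)],
            columns=list("abcd"),
        )
        expr["c"] = expr["a"]
        out = gs.gsva_scores(expr, {"s": ["g0", "g3", "g9"]})
        assert np.allclose(out["a"], out["c"])

    def test_matches_straight_line_recipe_on_toy_matrix(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=list("abcd"),
        )
        sets = {"toy": ["g1", "g4"]}
        out = gs.gsva_scores(expr, sets)
        expected = _gsva_by_hand(expr, set(sets["toy"]))
        assert np.allclose(out.loc["toy"].to_numpy(), expected, atol=1e-8)

    def test_column_order_invariance(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
            columns=list("abcde"),
        )
        sets = {"s": ["g2", "g5", "g11"]}
        out1 = gs.gsva_scores(expr, sets)
        out2 = gs.gsva_scores(expr[list("edcba")], sets)
        assert np.allclose(out1[list("abcde")].to_numpy(), out2[list("abcde")].to_numpy())

    def test_planted_pathway_scores_higher_in_treated_samples(self):
        """Pseudobulk per sample: the planted receiver program scores higher
        in treated than sham samples in >= 90% of 10 seeds."""
        from circuitscan import qc
        from circuitscan.simulate import SimConfig, generate_atlas
        from circuitscan.experiments import default_planted_circuits

        wins = []
        for seed in range(10):
            config = SimConfig(seed=seed, circuits=default_planted_circuits()[:1],
                               treatments=("sham", "CNP"))
            adata, truth = generate_atlas(config)
            adata = qc.filter_genes(adata)
            adata = qc.filter_cells(adata)
            adata = qc.lognormalize(adata)
            c = truth.circuits[0]
            mask = adata.obs["cell_type"] == c.receiver_type
            sub = adata[mask]
            L = pd.DataFrame(
                np.asarray(sub.layers["lognorm"]), index=sub.obs_names, columns=sub.var_names
            )
            pseudobulk = L.groupby(sub.obs["sample_id"].to_numpy()).mean().T
            out = gs.gsva_scores(pseudobulk, {"prog": list(c.targets)})
            treated = out.loc["prog", [s for s in out.columns if s.startswith("CNP")]]
            sham = out.loc["prog", [s for s in out.columns if s.startswith("sham")]]
            wins.append(float(treated.mean() > sham.mean()))
        assert np.mean(wins) >= 0.9

    def test_single_sample_rejected(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=["g0", "g1", "g2"])
        with pytest.raises(ValueError, match="2 samples"):
            gs.gsva_scores(expr, {"s": ["g0"]})


def _es_by_enumeration(values, hits, weight_p):
    """Literal running-sum enumeration of the weighted KS statistic."""
    order = np.argsort(-values, kind="stable")
    hit = np.isin(order, hits)
    w = np.abs(values[order]) ** weight_p
    denom = w[hit].sum()
    miss = 1.0 / (len(values) - hit.sum())
    v, best = 0.0, 0.0
    for i in range(len(values)):
        v = v + w[i] / denom if hit[i] else v - miss
        if abs(v) > abs(best):
            best = v
    return best


class TestGSEA:
    def test_all_hits_first_unweighted_es_is_one(self):
        ranking = pd.Series(np.arange(10, 0, -1, dtype=float),
                            index=[f"g{i}" for i in range(10)])
        res = gs.gsea_preranked(ranking, ["g0", "g1", "g2"], weight_p=0, n_perm=100, seed=0)
        assert res["es"] == pytest.approx(1.0)

    def test_es_matches_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            values = rng.normal(size=n)
            m = int(rng.integers(2, n // 2))
            hits = rng.choice(n, size=m, replace=False)
            genes = [f"g{i}" for i in range(n)]
            ranking = pd.Series(values, index=genes)
            for wp in (0.0, 1.0):
                res = gs.gsea_preranked(
                    ranking, [genes[i] for i in hits], weight_p=wp, n_perm=10, seed=0
                )
                assert res["es"] == pytest.approx(
                    _es_by_enumeration(values, hits, wp), abs=1e-10
                )

    def test_sign_reversal_negates_es(self, rng):
        values = rng.normal(size=30)
        genes = [f"g{i}" for i in range(30)]
        hits = [genes[i] for i in rng.choice(30, size=6, replace=False)]
        r1 = gs.gsea_preranked(pd.Series(values, index=genes), hits, n_perm=50, seed=0)
        r2 = gs.gsea_preranked(pd.Series(-values, index=genes), hits, n_perm=50, seed=0)
        assert r1["es"] == pytest.approx(-r2["es"], abs=1e-12)

    def test_nan_ranking_rejected(self):
        r = pd.Series([1.0, np.nan], index=["a", "b"])
        with pytest.raises(ValueError, match="NaN"):
            gs.gsea_preranked(r, ["a", "b"], n_perm=10, seed=0)

    def test_oversized_set_flagged(self):
        r = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="half"):
            gs.gsea_preranked(r, [f"g{i}" for i in range(6)], n_perm=10, seed=0)

    def test_collection_adds_bh_q(self, rng):
        values = rng.normal(size=50)
        genes = [f"g{i}" for i in range(50)]
        sets = {f"s{k}": [genes[i] for i in rng.choice(50, 8, replace=False)] for k in range(5)}
        out = gs.gsea_collection(pd.Series(values, index=genes), sets, n_perm=100, seed=0)
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestDotplotStats:
    def test_hand_arithmetic(self):
        L = np.array([[0.0], [0.0], [1.0], [3.0]])
        obs = pd.DataFrame(
            {"cell_type": ["A"] * 4, "treatment": ["CNP"] * 4},
            index=[f"c{i}" for i in range(4)],
        )
        a = _adata_lognorm(L, genes=["Cxcl1"], obs=obs)
        out = gs.dotplot_stats(a, ["Cxcl1"])
        assert out.iloc[0]["fraction_expressing"] == pytest.approx(0.5)
        assert out.iloc[0]["mean_expression"] == pytest.approx(1.0)

    def test_silent_group_gives_zeros(self):
        L = np.zeros((3, 2))
        L[:, 1] = 1.0
        obs = pd.DataFrame(
            {"cell_type": ["A"] * 3, "treatment": ["sham"] * 3},
            index=["c0", "c1", "c2"],
        )
        a = _adata_lognorm(L, obs=obs)
        out = gs.dotplot_stats(a, ["g0"])
        assert out.iloc[0]["fraction_expressing"] == 0.0
        assert out.iloc[0]["mean_expression"] == 0.0

    def test_fractions_bounded_and_unknown_genes_listed(self, planted_atlas):
        adata, _ = planted_atlas
        out = gs.dotplot_stats(adata, ["Cxcl1", "Il33"])
        assert out["fraction_expressing"].between(0, 1).all()
        with pytest.raises(KeyError, match="Nonexistent"):
            gs.dotplot_stats(adata, ["Cxcl1", "Nonexistent"])
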