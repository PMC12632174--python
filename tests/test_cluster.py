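"""Consensus HVGs, embedding, Leiden, markers, and two-tier annotation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from circuitscan import cluster
from circuitscan._stats import wilcoxon_rank_sum


def _lognorm_adata(L, samples, genes=None):
    L = np.asarray(L, dtype=float)
    genes = genes or [f"g{i}" for i in range(L.shape[1])]
    a = ad.AnnData(
        X=sp.csr_matrix(np.expm1(L)),
        obs=pd.DataFrame({"sample_id": samples},
                         index=[f"c{i}" for i in range(L.shape[0])]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    a.layers["lognorm"] = L
    return a


class TestConsensusHVG:
    def test_consensus_is_genes_flagged_in_two_or_more_samples(self, planted_atlas):
        """The consensus list is exactly the genes whose per-sample HVG flag
        count reaches 2; genes flagged in a single sample are excluded."""
        adata, _ = planted_atlas
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        counts = sel.per_sample.sum(axis=1)
        assert set(sel.consensus) == set(counts.index[counts >= 2])
        singletons = set(counts.index[counts == 1])
        assert singletons, "need singleton-flagged genes for this check"
        assert not (singletons & set(sel.consensus))
        assert set(sel.consensus) <= set(counts.index[counts > 0])

    def test_planted_markers_reach_consensus(self, planted_atlas):
        """Marker genes are bimodal across types in every sample, so they are
        flagged everywhere and must survive the >= 2-sample consensus rule."""
        adata, _ = planted_atlas
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        markers = {g for g in adata.var_names if g.startswith("mk_")}
        assert len(markers & set(sel.consensus)) >= 0.9 * len(markers)

    def test_identical_samples_consensus_equals_per_sample_set(self, rng):
        L = rng.gamma(2.0, 0.5, size=(30, 50))
        a = _lognorm_adata(np.vstack([L, L]), ["a"] * 30 + ["b"] * 30)
        sel = cluster.select_hvgs_consensus(a, n_top=10)
        assert set(sel.consensus) == set(sel.per_sample.index[sel.per_sample["a"]])

    def test_constant_gene_never_hvg(self, rng):
        L = rng.gamma(2.0, 0.5, size=(60, 50))
        L[:, 7] = 1.0
        a = _lognorm_adata(L, ["a"] * 30 + ["b"] * 30)
        sel = cluster.select_hvgs_consensus(a, n_top=20)
        assert "g7" not in sel.consensus

    def test_single_sample_rejected(self, rng):
        a = _lognorm_adata(rng.gamma(2.0, 0.5, size=(30, 40)), ["a"] * 30)
        with pytest.raises(ValueError, match="2 samples"):
            cluster.select_hvgs_consensus(a)


class TestEmbedAndGraph:
    def test_duplicated_cells_get_identical_coordinates(self, rng):
        L = rng.gamma(2.0, 0.5, size=(40, 30))
        L[1] = L[0]
        a = _lognorm_adata(L, ["a"] * 20 + ["b"] * 20)
        pcs, _ = cluster.embed_and_graph(a, list(a.var_names), n_pcs=10, k=5)
        assert np.allclose(pcs[0], pcs[1], atol=1e-8)

    def test_pc_variance_ordering(self, rng):
        L = rng.gamma(2.0, 0.5, size=(60, 30))
        a = _lognorm_adata(L, ["a"] * 30 + ["b"] * 30)
        pcs, _ = cluster.embed_and_graph(a, list(a.var_names), n_pcs=10, k=5)
        var = pcs.var(axis=0)
        assert (np.diff(var) <= 1e-10).all()
        assert var.sum() <= 30 * (60 / 59) + 1e-6  # total scaled variance bound

    def test_knn_graph_separates_planted_types(self, planted_atlas):
        """Modularity of the true labels beats 100 random label permutations."""
        import igraph
        adata, _ = planted_atlas
        adata = adata.copy()
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        _, conn = cluster.embed_and_graph(adata, sel.consensus, seed=0)
        A = sp.csr_matrix(conn).maximum(sp.csr_matrix(conn).T)
        src, dst = A.nonzero()
        keep = src < dst
        g = igraph.Graph(n=A.shape[0], edges=list(zip(src[keep], dst[keep])))
        labels = pd.Categorical(adata.obs["true_cell_type"]).codes
        q_true = g.modularity(labels)
        rng = np.random.default_rng(0)
        q_perm = [g.modularity(rng.permutation(labels)) for _ in range(100)]
        assert q_true > max(q_perm)

    def test_too_many_neighbors_rejected(self, rng):
        a = _lognorm_adata(rng.gamma(2.0, 0.5, size=(10, 20)), ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="neighbors"):
            cluster.embed_and_graph(a, list(a.var_names), k=10)


class TestLeiden:
    def test_two_disconnected_cliques_give_two_clusters(self):
        n = 10
        A = np.zeros((2 * n, 2 * n))
        A[:n, :n] = 1
        A[n:, n:] = 1
        np.fill_diagonal(A, 0)
        for res in (0.1, 0.5, 1.0):
            labels = cluster.cluster_leiden(sp.csr_matrix(A), resolution=res, seed=0)
            assert len(set(labels)) == 2
            assert len(set(labels[:n])) == 1 and len(set(labels[n:])) == 1

    def test_deterministic_given_seed(self, planted_atlas):
        adata, _ = planted_atlas
        adata = adata.copy()
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        _, conn = cluster.embed_and_graph(adata, sel.consensus, seed=0)
        l1 = cluster.cluster_leiden(conn, seed=3)
        l2 = cluster.cluster_leiden(conn, seed=3)
        assert np.array_equal(l1, l2)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster.cluster_leiden(sp.csr_matrix((0, 0)))

    def test_recovers_planted_types(self, planted_atlas):
        adata, _ = planted_atlas
        adata = adata.copy()
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        _, conn = cluster.embed_and_graph(adata, sel.consensus, seed=0)
        labels = cluster.cluster_leiden(conn, seed=0)
        ari = adjusted_rand_score(adata.obs["true_cell_type"], labels)
        assert ari >= 0.9


class TestMarkers:
    def test_identical_group_distributions_give_p_near_one(self, rng):
        """Genes whose value multiset is identical in cluster and rest have
        balanced rank sums: mean two-sided p >= 0.9 over 20 such genes at
        n = 50 per group, and nothing is flagged as a marker."""
        v = rng.gamma(2.0, 0.5, size=(50, 20))
        L = np.vstack([v, rng.permutation(v, axis=0)])
        a = _lognorm_adata(L, ["a"] * 50 + ["b"] * 50)
        labels = np.array([0] * 50 + [1] * 50)
        table = cluster.rank_markers_wilcoxon(a, labels, top_n=None)
        assert table[table["cluster"] == 0]["p"].mean() >= 0.9
        assert not table["is_marker"].any()

    def test_exact_enumeration_small_samples(self):
        """n=3 vs 3, no ties: p matches enumeration of all 20 rank splits."""
        from itertools import combinations

        x = np.array([1.3, 2.9, 0.4])
        y = np.array([2.1, 3.8, 5.0])
        _, p = wilcoxon_rank_sum(x, y, method="exact")
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs_r1 = ranks[:3].sum()
        null_r1 = [sum(c) for c in combinations(ranks, 3)]
        mu = np.mean(null_r1)
        p_enum = np.mean([abs(r - mu) >= abs(obs_r1 - mu) - 1e-12 for r in null_r1])
        assert p == pytest.approx(p_enum, abs=1e-12)

    def test_marker_flag_requires_both_thresholds(self, planted_atlas):
        adata, _ = planted_atlas
        table = cluster.rank_markers_wilcoxon(
            adata, adata.obs["true_cell_type"].to_numpy(), top_n=None
        )
        flagged = table[table["is_marker"]]
        assert (flagged["q"] < 0.05).all() and (flagged["log2FC"] > 0.5).all()
        weak_lfc = table[(table["q"] < 0.05) & (table["log2FC"] <= 0.5)]
        assert len(weak_lfc) > 0 and not weak_lfc["is_marker"].any()

    def test_planted_markers_in_top500(self, planted_atlas):
        adata, truth = planted_atlas
        table = cluster.rank_markers_wilcoxon(
            adata, adata.obs["true_cell_type"].to_numpy(), top_n=500
        )
        for ct in truth.cell_types:
            top = set(table[table["cluster"] == ct]["gene"])
            planted = {g for g in adata.var_names if g.startswith(f"mk_{ct}_")}
            assert planted <= top

    def test_bh_monotone_step_up(self, planted_atlas):
        adata, _ = planted_atlas
        table = cluster.rank_markers_wilcoxon(
            adata, adata.obs["true_cell_type"].to_numpy(), top_n=None
        )
        grp = table[table["cluster"] == table["cluster"].iloc[0]].sort_values("p")
        assert (grp["q"].to_numpy() >= grp["p"].to_numpy() - 1e-15).all()
        assert grp["q"].max() <= 1.0
        assert (np.diff(grp["q"].to_numpy()) >= -1e-12).all()


class TestAnnotate:
    def test_two_tier_annotation_recovers_planted_types(self, planted_atlas):
        adata, truth = planted_atlas
        adata = adata.copy()
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        _, conn = cluster.embed_and_graph(adata, sel.consensus, seed=0)
        labels = cluster.cluster_leiden(conn, seed=0)
        ref = cluster.default_marker_reference(truth)
        obs = cluster.annotate_types(adata, labels, ref, seed=0)
        truth_labels = adata.obs["true_cell_type"].to_numpy()
        assert (obs["cell_type"].to_numpy() == truth_labels).mean() >= 0.95
        # lineage assignment follows the defining genes
        expected_lineage = pd.Series(truth_labels).map(truth.lineages).to_numpy()
        assert (obs["lineage"].to_numpy() == expected_lineage).mean() >= 0.95
        # niche follows the reference map
        assert (obs["niche"].to_numpy()
                == pd.Series(obs["cell_type"]).map(truth.niches).to_numpy()).all()

    def test_fine_type_never_leaves_lineage(self, planted_atlas):
        adata, truth = planted_atlas
        adata = adata.copy()
        sel = cluster.select_hvgs_consensus(adata, n_top=300)
        _, conn = cluster.embed_and_graph(adata, sel.consensus, seed=0)
        labels = cluster.cluster_leiden(conn, seed=0)
        ref = cluster.default_marker_reference(truth)
        obs = cluster.annotate_types(adata, labels, ref, seed=0)
        for _, row in obs.iterrows():
            assert ref.fine_lineage[row["cell_type"]] == row["lineage"]

    def test_exact_tie_broken_by_fixed_lineage_order(self, rng):
        # two defining genes with identical expression: epithelial wins
        genes = ["Epcam", "Cldn5", "Col1a2", "Ptprc", "mk_A_0"]
        L = np.zeros((20, 5))
        L[:, 0] = 2.0  # Epcam
        L[:, 1] = 2.0  # Cldn5, exact tie
        L[:, 4] = rng.gamma(2.0, 0.5, size=20)
        a = _lognorm_adata(L, ["s1"] * 10 + ["s2"] * 10, genes=genes)
        ref = cluster.MarkerReference(
            fine_markers={"A": ["mk_A_0"]},
            fine_lineage={"A": "epithelial"},
            niche_map={"A": "n"},
        )
        obs = cluster.annotate_types(a, np.zeros(20, dtype=int), ref, seed=0)
        assert (obs["lineage"] == "epithelial").all()

    def test_missing_lineage_gene_errors(self, rng):
        a = _lognorm_adata(rng.gamma(2.0, 0.5, size=(10, 4)),
                           ["a"] * 5 + ["b"] * 5, genes=["Epcam", "Cldn5", "Col1a2", "g3"])
        ref = cluster.MarkerReference(fine_markers={}, fine_lineage={}, niche_map={})
        with pytest.raises(ValueError, match="Ptprc"):
            cluster.annotate_types(a, np.zeros(10, dtype=int), ref, seed=0)
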