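"""Clustering stack: feature selection, batch standardization, PCA, SNN
graph, Louvain communities, and overrepresentation testing."""

import numpy as np
import pandas as pd
import pytest

import citeflow as cf
from citeflow.cluster import _relabel_by_size
from citeflow.normalize import NormalizedMatrix


def _nm(values, cells=None):
    values = np.asarray(values, dtype=float)
    cells = cells if cells is not None else pd.RangeIndex(values.shape[0])
    return NormalizedMatrix(values, pd.Index(cells),
                            pd.Index([f"f{j}" for j in range(values.shape[1])]),
                            "test")


class TestVariableFeatures:
    def test_single_batch_is_top_variance(self):
        rng = np.random.default_rng(0)
        V = rng.normal(0, 1, (50, 10))
        V[:, 3] *= 5
        V[:, 7] *= 3
        feats = cf.select_variable_features(_nm(V), n=2)
        assert set(feats) == {"f3", "f7"}

    def test_constant_feature_never_selected(self):
        rng = np.random.default_rng(1)
        V = rng.normal(0, 1, (30, 5))
        V[:, 2] = 0.0
        feats = cf.select_variable_features(_nm(V), n=4)
        assert "f2" not in set(feats)

    def test_all_features_with_warning_when_n_too_large(self):
        with pytest.warns(UserWarning, match="available"):
            feats = cf.select_variable_features(_nm(np.eye(4)), n=10)
        assert len(feats) == 4

    def test_markers_survive_median_rank_aggregation(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            V = rng.normal(0, 1, (90, 30))
            V[:, :3] *= 4  # planted high-variance markers
            batches = pd.Series(np.repeat(["a", "b", "c"], 30))
            feats = cf.select_variable_features(_nm(V), batches, n=5)
            hits += {"f0", "f1", "f2"} <= set(feats)
        assert hits >= 9


class TestBatchStandardize:
    def test_single_batch_equals_center_scale(self):
        rng = np.random.default_rng(2)
        m = _nm(rng.normal(2, 3, (40, 6)))
        b = pd.Series(["x"] * 40)
        out = cf.batch_standardize(m, b)
        ref = cf.center_scale(m)
        assert np.allclose(out.values, ref.values)

    def test_additive_batch_offsets_removed(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, (60, 4))
        off = np.repeat([0.0, 5.0, -3.0], 20)[:, None]
        m = _nm(base + off)
        b = pd.Series(np.repeat(["a", "b", "c"], 20))
        out = cf.batch_standardize(m, b)
        for batch in "abc":
            assert np.abs(out.values[(b == batch).to_numpy()].mean(axis=0)).max() < 1e-12

    def test_batch_not_separable_in_embedding(self):
        """After per-batch standardization a linear probe cannot predict
        batch from the leading PCs better than chance."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_predict

        cfg = cf.SimConfig(n_healthy=4, n_as=4, cells_per_subject=100,
                           n_genes=60, n_mito=3, n_ribo=10, n_batches=2,
                           batch_sigma=0.4, artifact_fold=1.0,
                           cell_types=(cf.CellTypeSpec("T", 1.0, 0.0),), seed=4)
        ds = cf.generate_cohort(cfg)
        vst = cf.vst_residuals(ds.rna)
        batches = ds.rna.obs["batch"].astype(str)
        std = cf.batch_standardize(
            NormalizedMatrix(vst.values, vst.cells, vst.features, "t"), batches)
        scores, _, _ = cf.pca_embed(std, 5)
        y = (batches == "batch1").to_numpy().astype(int)
        prob = cross_val_predict(LogisticRegression(max_iter=1000), scores, y,
                                 cv=5, method="predict_proba")[:, 1]
        assert abs(cf.auroc(prob, y) - 0.5) < 0.1


class TestPCA:
    def test_one_axis_of_variation(self):
        t = np.linspace(-2, 2, 30)
        V = np.outer(t, [1.0, 2.0, -1.0])
        scores, _, ev = cf.pca_embed(_nm(V), 3)
        assert np.abs(scores[:, 1:]).max() < 1e-10
        assert ev[0] > 0 and ev[1] == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_scores_and_eigensolver_oracle(self):
        rng = np.random.default_rng(5)
        V = rng.normal(0, 1, (20, 10))
        scores, load, ev = cf.pca_embed(_nm(V), 5)
        G = scores.T @ scores
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        # oracle: dense eigendecomposition of the covariance matrix
        C = np.cov(V, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1][:5]
        assert np.allclose(ev, eig, atol=1e-10)

    def test_n_pcs_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            scores, _, _ = cf.pca_embed(_nm(np.eye(3)), 10)
        assert scores.shape == (3, 3)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(6)
        V = rng.normal(0, 1, (25, 8))
        _, load1, _ = cf.pca_embed(_nm(V), 4)
        _, load2, _ = cf.pca_embed(_nm(V.copy()), 4)
        assert np.allclose(load1, load2)
        for k in range(4):
            j = np.argmax(np.abs(load1[:, k]))
            assert load1[j, k] > 0


class TestSNN:
    def _blobs(self, sep=10.0, n=30, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 3))
        b = rng.normal(sep, 1, (n, 3))
        return np.vstack([a, b])

    def test_separated_blobs_have_no_cross_edges(self):
        X = self._blobs()
        g = cf.snn_graph(X, k=10)
        for e in g.es:
            assert (e.source < 30) == (e.target < 30)

    def test_graph_is_undirected_with_jaccard_weights(self):
        X = self._blobs(sep=3.0)
        g = cf.snn_graph(X, k=8)
        assert not g.is_directed()
        assert all(0 < w <= 1 for w in g.es["weight"])

    def test_k_must_be_less_than_n(self):
        with pytest.raises(ValueError, match="k="):
            cf.snn_graph(np.zeros((5, 2)), k=5)


class TestLouvain:
    def test_two_disconnected_cliques(self):
        import igraph
        g = igraph.Graph.Full(20) + igraph.Graph.Full(20)
        g.es["weight"] = 1.0
        res = cf.louvain_cluster(g, seed=0)
        assert res.n_clusters == 2
        labels = res.labels.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_modularity_beats_trivial_partitions(self):
        X = TestSNN()._blobs(sep=4.0, seed=1)
        g = cf.snn_graph(X, k=10)
        res = cf.louvain_cluster(g, seed=0)
        q = g.modularity(res.labels.to_numpy(), weights="weight")
        q_single = g.modularity([0] * g.vcount(), weights="weight")
        q_singleton = g.modularity(list(range(g.vcount())), weights="weight")
        assert q >= q_single and q >= q_singleton

    def test_seeded_determinism_and_size_sorted_labels(self):
        X = TestSNN()._blobs(sep=2.0, seed=2)
        g = cf.snn_graph(X, k=10)
        a = cf.louvain_cluster(g, seed=7)
        b = cf.louvain_cluster(g, seed=7)
        assert a.labels.equals(b.labels)
        sizes = a.labels.value_counts().sort_index()
        assert list(sizes) == sorted(sizes, reverse=True)

    def test_edgeless_graph_gives_singletons(self):
        import igraph
        with pytest.warns(UserWarning, match="no edges"):
            res = cf.louvain_cluster(igraph.Graph(n=4), seed=0)
        assert res.n_clusters == 4

    def test_relabel_by_size_tie_break(self):
        lab = _relabel_by_size(np.array([5, 5, 9, 9, 1]))
        assert lab.tolist() == [0, 0, 1, 1, 2]


def test_planted_subcluster_recovered_with_high_ari():
    """A strongly marked subset inside one cell type is recovered as a
    Louvain cluster (binary ARI vs truth >= 0.8)."""
    from sklearn.metrics import adjusted_rand_score

    sc = cf.SubclusterSpec(parent="NK", rna_markers=tuple(
        f"GENE{i:04d}" for i in range(1, 9)), adt_markers=("CD16",),
        marker_log2fc=3.0, base_rate=0.15, as_enrichment=3.0)
    cfg = cf.SimConfig(n_healthy=5, n_as=5, cells_per_subject=120,
                       n_genes=80, n_mito=4, n_ribo=12, n_batches=2,
                       artifact_fold=1.0, subcluster_spec=sc,
                       cell_types=(cf.CellTypeSpec("NK", 0.5, 0.4),
                                   cf.CellTypeSpec("T", 0.5, 0.4)), seed=8)
    ds = cf.generate_cohort(cfg)
    nk = ds.rna[(ds.rna.obs["cell_type"] == "NK").to_numpy()].copy()
    truth = nk.obs_names.isin(ds.truth.planted_subcluster).astype(int)
    vst = cf.vst_residuals(nk)
    std = cf.batch_standardize(
        NormalizedMatrix(vst.values, vst.cells, vst.features, "t"),
        nk.obs["batch"].astype(str))
    scores, _, _ = cf.pca_embed(std, 10)
    g = cf.snn_graph(scores, k=20)
    res = cf.louvain_cluster(g, resolution=0.6, seed=0)
    # binary comparison against the best-matching cluster
    best_ari = max(
        adjusted_rand_score(truth, (res.labels.to_numpy() == c).astype(int))
        for c in range(res.n_clusters))
    assert best_ari >= 0.8


class TestOverrepresentation:
    def _result(self, labels, cells):
        return cf.ClusterResult(labels=pd.Series(labels),
                                embedding=np.zeros((len(cells), 0)))

    def test_separated_cluster_fractions_reach_smallest_exact_p(self):
        # 10 parent cells per subject; AS fractions {0.6..1.0} all above
        # healthy fractions {0..0.4}, untied, so the exact branch applies
        rows, labels = [], []
        for i in range(5):
            rows += [(f"AS{i}", "AS")] * 10
            labels += [0] * (6 + i) + [1] * (4 - i)
        for i in range(5):
            rows += [(f"H{i}", "healthy")] * 10
            labels += [0] * i + [1] * (10 - i)
        meta = pd.DataFrame(rows, columns=["subject", "cohort"])
        res = self._result(labels, meta)
        out = cf.cluster_overrepresentation(res, meta)
        # complete separation of 5 vs 5 fractions: exact p = 2/C(10,5)
        assert out.loc["cluster0", "p"] == pytest.approx(2 / 252)

    def test_single_cluster_everything_p_one(self):
        meta = pd.DataFrame({"subject": ["a", "a", "b", "b"],
                             "cohort": ["AS", "AS", "healthy", "healthy"]})
        res = self._result([0, 0, 0, 0], meta)
        with pytest.warns(UserWarning, match="tied"):
            out = cf.cluster_overrepresentation(res, meta)
        assert out.loc["cluster0", "p"] == 1.0
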