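"""Subject-level ML: feature matrices, splitting, ensemble selection,
training, evaluation metrics, and the no-leakage contract."""

import numpy as np
import pandas as pd
import pytest

import citeflow as cf
from citeflow import mlpipe


def _labels(n_h=29, n_as=10):
    idx = [f"H{i:02d}" for i in range(n_h)] + [f"AS{i:02d}" for i in range(n_as)]
    return pd.Series(["healthy"] * n_h + ["AS"] * n_as, index=idx)


def _toy_matrix(n_h=20, n_as=20, d_noise=8, effect=2.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = _labels(n_h, n_as)
    X = rng.normal(0, 1, (n_h + n_as, d_noise + 2))
    X[n_h:, 0] += effect
    X[n_h:, 1] -= effect
    cols = [f"T|RNA|g{j}" for j in range(d_noise + 2)]
    return mlpipe.SubjectFeatureMatrix(
        pd.DataFrame(X, index=labels.index, columns=cols), labels)


class TestBuildFeatureMatrix:
    def _inputs(self):
        cells = [f"c{i}" for i in range(6)]
        expr = pd.DataFrame({"g1": [1.0, 2.0, 3.0, 10.0, 10.0, 10.0]},
                            index=cells)
        de = pd.DataFrame([{"feature": "g1", "cell_type": "T",
                            "modality": "RNA", "significant": True}])
        subj = pd.Series(["s1"] * 3 + ["s2"] * 3, index=cells)
        labels = pd.Series({"s1": "AS", "s2": "healthy", "s3": "AS"})
        return expr, de, subj, labels

    def test_subject_mean_and_missing_subject_nan(self):
        expr, de, subj, labels = self._inputs()
        m = mlpipe.build_feature_matrix({("T", "RNA"): expr}, de, subj, labels)
        assert m.values.loc["s1", "T|RNA|g1"] == pytest.approx(2.0)
        assert np.isnan(m.values.loc["s3", "T|RNA|g1"])  # no cells of type T

    def test_imputation_uses_training_subjects_only(self):
        expr, de, subj, labels = self._inputs()
        m = mlpipe.build_feature_matrix({("T", "RNA"): expr}, de, subj, labels)
        filled = mlpipe.impute_missing(m, pd.Index(["s1"]))
        # train mean is s1's value (2.0), not the global mean (6.0)
        assert filled.values.loc["s3", "T|RNA|g1"] == pytest.approx(2.0)
        assert filled.imputed.loc["s3", "T|RNA|g1"]
        assert not filled.imputed.loc["s1", "T|RNA|g1"]

    def test_absent_de_feature_is_named(self):
        expr, de, subj, labels = self._inputs()
        de2 = pd.concat([de, pd.DataFrame([{"feature": "gX", "cell_type": "T",
                                            "modality": "RNA",
                                            "significant": True}])])
        with pytest.raises(ValueError, match="gX"):
            mlpipe.build_feature_matrix({("T", "RNA"): expr}, de2, subj, labels)

    def test_width_is_count_of_significant_features(self):
        expr, de, subj, labels = self._inputs()
        expr = expr.assign(g2=1.0, g3=2.0)
        de3 = pd.DataFrame([
            {"feature": f, "cell_type": "T", "modality": "RNA",
             "significant": s}
            for f, s in (("g1", True), ("g2", True), ("g3", False))])
        m = mlpipe.build_feature_matrix({("T", "RNA"): expr}, de3, subj, labels)
        assert m.values.shape[1] == 2


class TestStratifiedSplit:
    def test_study_cohort_sizes(self):
        labels = _labels(29, 10)
        train, test = mlpipe.stratified_split(labels, seed=0)
        assert (labels[train] == "healthy").sum() == 15
        assert (labels[train] == "AS").sum() == 5
        assert (labels[test] == "healthy").sum() == 14
        assert (labels[test] == "AS").sum() == 5
        assert len(set(train) & set(test)) == 0

    def test_two_per_class_minimum(self):
        labels = pd.Series(["AS", "AS", "healthy", "healthy"],
                           index=list("abcd"))
        train, test = mlpipe.stratified_split(labels, seed=1)
        assert len(train) == 2 and len(test) == 2
        with pytest.raises(ValueError, match="fewer than 2"):
            mlpipe.stratified_split(pd.Series(["AS", "healthy", "healthy"],
                                              index=list("abc")), 0)

    def test_seed_determinism_and_variation(self):
        labels = _labels(8, 4)
        t1, _ = mlpipe.stratified_split(labels, seed=5)
        t2, _ = mlpipe.stratified_split(labels, seed=5)
        assert list(t1) == list(t2)
        others = [tuple(mlpipe.stratified_split(labels, seed=s)[0])
                  for s in range(10)]
        assert len(set(others)) > 1


class TestEnsembleSelect:
    def test_n_top_contract_and_tie_break(self):
        m = _toy_matrix(seed=1)
        sel = mlpipe.ensemble_select(m.values, m.labels, 5, seed=0)
        assert len(sel.selected) == 5
        assert set(sel.table.columns) >= {"aggregate"}
        agg = sel.table["aggregate"]
        assert (agg.diff().dropna() <= 1e-12).all()  # monotone ranking

    def test_single_selector_equals_its_own_order(self):
        m = _toy_matrix(seed=2)
        only = {"rfe_rf": mlpipe.SELECTORS["rfe_rf"]}
        sel = mlpipe.ensemble_select(m.values, m.labels, 4, seed=0,
                                     selectors=only)
        imp = sel.table["rfe_rf"]
        assert list(sel.table["aggregate"]) == list(imp)

    def test_informative_features_rank_top(self):
        hits = 0
        seeds = 5
        for seed in range(seeds):
            m = _toy_matrix(n_h=20, n_as=20, d_noise=20, effect=2.0,
                            seed=10 + seed)
            sel = mlpipe.ensemble_select(m.values, m.labels, 5, seed=seed)
            top5 = set(sel.selected)
            hits += {"T|RNA|g0", "T|RNA|g1"} <= top5
        assert hits >= 0.9 * seeds

    def test_n_top_exceeding_width_rejected(self):
        m = _toy_matrix()
        with pytest.raises(ValueError, match="n_top"):
            mlpipe.ensemble_select(m.values, m.labels, 99, seed=0)


class TestTrainEvaluate:
    def test_separable_toy_all_models_cv_accurate(self):
        m = _toy_matrix(n_h=20, n_as=20, d_noise=2, effect=4.0, seed=3)
        roster = mlpipe.get_roster(("glm", "lda", "glmnet", "knn", "cart",
                                    "rf", "svmRadial", "nb", "avNNet"), 0)
        models = mlpipe.train_models(m.values, m.labels, roster, seed=0)
        for name, entry in models.items():
            assert entry["cv_accuracy_mean"] >= 0.9, name

    def test_permuted_labels_give_near_zero_kappa(self):
        kappas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            m = _toy_matrix(n_h=12, n_as=12, d_noise=4, effect=0.0, seed=seed)
            roster = mlpipe.get_roster(("glm", "nb"), seed)
            models = mlpipe.train_models(m.values, m.labels, roster, seed=seed)
            kappas += [e["cv_kappa_mean"] for e in models.values()]
        assert abs(np.mean(kappas)) < 0.15

    def test_fixed_seed_reproduces_cv_metrics(self):
        m = _toy_matrix(seed=4)
        roster = mlpipe.get_roster(("rf",), 1)
        a = mlpipe.train_models(m.values, m.labels, roster, seed=9)
        b = mlpipe.train_models(m.values, m.labels, roster, seed=9)
        assert a["rf"]["cv_accuracy_mean"] == b["rf"]["cv_accuracy_mean"]
        assert a["rf"]["best_params"] == b["rf"]["best_params"]


class TestMetrics:
    def test_auroc_perfect_and_hand_value(self):
        assert mlpipe.auroc([0.9, 0.8, 0.1, 0.2, 0.3],
                            [1, 1, 0, 0, 0]) == 1.0
        assert mlpipe.auroc([0.9, 0.25, 0.1, 0.2, 0.3],
                            [1, 1, 0, 0, 0]) == pytest.approx(5 / 6)

    def test_auroc_equals_normalized_mann_whitney_u(self):
        from scipy import stats
        rng = np.random.default_rng(7)
        for _ in range(10):
            scores = rng.normal(size=30)
            scores[:12] += rng.uniform(0, 1)
            y = np.zeros(30, dtype=int)
            y[:12] = 1
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0],
                                   alternative="two-sided").statistic
            assert mlpipe.auroc(scores, y) == pytest.approx(u / (12 * 18))

    def test_kappa_hand_value(self):
        assert mlpipe.cohen_kappa(tp=4, fn=1, fp=1, tn=13) == \
            pytest.approx(0.7286, abs=1e-4)

    def test_label_swap_maps_sensitivity_to_specificity(self):
        m = _toy_matrix(n_h=10, n_as=10, d_noise=2, effect=1.0, seed=5)
        roster = mlpipe.get_roster(("glm",), 0)
        models = mlpipe.train_models(m.values, m.labels, roster, seed=0)
        rep_as = mlpipe.evaluate_models(models, m.values, m.labels,
                                        positive="AS")["glm"]
        models_h = mlpipe.train_models(m.values, m.labels, roster, seed=0,
                                       positive="healthy")
        rep_h = mlpipe.evaluate_models(models_h, m.values, m.labels,
                                       positive="healthy")["glm"]
        assert rep_as["accuracy"] == pytest.approx(rep_h["accuracy"])
        assert rep_as["kappa"] == pytest.approx(rep_h["kappa"], abs=1e-9)
        assert rep_as["sensitivity"] == pytest.approx(rep_h["specificity"])
        assert rep_as["specificity"] == pytest.approx(rep_h["sensitivity"])


class TestRunMl:
    def test_no_leakage_selection_sees_training_subjects_only(self, monkeypatch):
        m = _toy_matrix(n_h=10, n_as=6, d_noise=4, seed=6)
        seen = {}
        orig = mlpipe.ensemble_select

        def spy(X, y, n_top, seed, selectors=None):
            seen["subjects"] = set(X.index)
            return orig(X, y, n_top, seed, selectors)

        monkeypatch.setattr(mlpipe, "ensemble_select", spy)
        out = mlpipe.run_ml(m, n_top=4, seed=0, roster_names=("glm", "nb"))
        train = set(out["train_subjects"])
        test = set(out["test_subjects"])
        assert seen["subjects"] == train
        assert train.isdisjoint(test)

    def test_null_features_give_chance_level_auroc(self):
        aurocs = []
        for seed in range(3):
            m = _toy_matrix(n_h=16, n_as=10, d_noise=10, effect=0.0,
                            seed=30 + seed)
            out = mlpipe.run_ml(m, n_top=6, seed=seed,
                                roster_names=("glm", "nb", "knn"))
            aurocs.append(np.mean([r["auroc"]
                                   for r in out["report"].values()]))
        assert abs(np.mean(aurocs) - 0.5) <= 0.25


class TestProfileProvenance:
    def test_subject_profile_matrix_matches_de_width_and_runs(self):
        """The within-subject log-profile provenance yields the same
        feature ids as the scaled-mean matrix and supports the same ML
        path — the leakage check on the default normalization."""
        import citeflow as cf

        simcfg = cf.SimConfig(n_healthy=8, n_as=6, cells_per_subject=60,
                              n_genes=80, n_mito=4, n_ribo=12, n_adt=12,
                              seed=17)
        ds = cf.generate_cohort(simcfg)
        de = pd.DataFrame([
            {"feature": "GENE0001", "cell_type": "CD4 T", "modality": "RNA",
             "significant": True},
            {"feature": "CD3", "cell_type": "CD4 T", "modality": "ADT",
             "significant": True},
            {"feature": "GENE0002", "cell_type": "NK", "modality": "RNA",
             "significant": True},
        ])
        m = mlpipe.build_profile_matrix(ds.rna, ds.adt, de,
                                        ds.subject_meta["cohort"])
        assert m.provenance == "subject-logcpm"
        assert set(m.values.columns) == {"CD4 T|RNA|GENE0001",
                                         "CD4 T|ADT|CD3", "NK|RNA|GENE0002"}
        out = mlpipe.run_ml(m, n_top=2, seed=0, roster_names=("glm", "nb"))
        assert 0.0 <= out["best_auroc"] <= 1.0

    def test_profile_values_follow_log_formula(self):
        import citeflow as cf

        simcfg = cf.SimConfig(n_healthy=2, n_as=2, cells_per_subject=40,
                              n_genes=60, n_mito=3, n_ribo=9, n_adt=10,
                              cell_types=(cf.CellTypeSpec("T", 1.0, 0.0),),
                              seed=18)
        ds = cf.generate_cohort(simcfg)
        de = pd.DataFrame([{"feature": "GENE0001", "cell_type": "T",
                            "modality": "RNA", "significant": True}])
        m = mlpipe.build_profile_matrix(ds.rna, ds.adt, de,
                                        ds.subject_meta["cohort"])
        subj = ds.subject_meta.index[0]
        cells = (ds.rna.obs["subject"] == subj).to_numpy()
        X = np.asarray(ds.rna[cells].X.todense())
        j = list(ds.rna.var_names).index("GENE0001")
        count = max(X[:, j].sum(), 1.0)
        expect = np.log(count / X.sum() * 1e7)
        assert m.values.loc[subj, "T|RNA|GENE0001"] == pytest.approx(expect)
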