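"""Subject-level classification of disease status.

The ML input is a subjects × features matrix of pseudobulk values: for each
cell-type-specific differentially expressed gene or protein, the mean of
its scaled normalized expression over each subject's cells of that type
(subjects without cells of a type are imputed with the training-cohort
mean).  Subjects are split 50:50 into training and test halves stratified
by cohort (ceil of each class to training, reproducing a 15/5 train vs
14/5 test split for a 29/10 cohort).  Ensemble feature selection combines
four selectors — forward/backward stepwise selection, recursive-elimination
random forest, radial-kernel SVM permutation weighting, and a small neural
network's permutation weighting — each contributing a per-feature
importance normalized to sum to one; features are ranked by the mean
normalized importance.  A nine-model roster spanning linear, non-linear and
ensemble families is tuned by repeated stratified cross-validation
(5-fold × 2 by default, 10-fold × 10 selectable) and evaluated on the
held-out half with accuracy, sensitivity, specificity, F1, Cohen's kappa
and AUROC (pairwise concordance; ties count one half).

Everything fitted — imputation means, standardization, selectors,
hyperparameters — sees training subjects only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (BaggingClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.feature_selection import RFE
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, make_scorer
from sklearn.model_selection import (GridSearchCV, RepeatedStratifiedKFold,
                                     StratifiedKFold, cross_val_score)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["SubjectFeatureMatrix", "SelectionResult", "build_feature_matrix",
           "impute_missing", "stratified_split", "ensemble_select",
           "get_roster", "train_models", "evaluate_models", "auroc",
           "cohen_kappa", "run_ml"]


@dataclass
class SubjectFeatureMatrix:
    """Subjects × (cell type : modality : feature) pseudobulk table."""

    values: pd.DataFrame
    labels: pd.Series  # subject -> cohort
    provenance: str = "scaled-mean"
    imputed: pd.DataFrame | None = None  # boolean mask, set after imputation

    def __post_init__(self) -> None:
        if self.labels.reindex(self.values.index).isna().any():
            raise ValueError("missing cohort labels for some subjects")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")


@dataclass
class SelectionResult:
    table: pd.DataFrame  # per-feature importance per selector + aggregate
    selected: list[str]
    n_top: int


FEATURE_SEP = "|"


def feature_id(cell_type: str, modality: str, feature: str) -> str:
    return FEATURE_SEP.join([cell_type, modality, feature])


def build_feature_matrix(scaled_expr: dict, de: pd.DataFrame,
                         cell_subjects: pd.Series, labels: pd.Series,
                         provenance: str = "scaled-mean"
                         ) -> SubjectFeatureMatrix:
    """Pseudobulk means of significant DE features.

    ``scaled_expr`` maps (cell_type, modality) → cells × features DataFrame
    of scaled values for the cells of that type; ``cell_subjects`` maps cell
    barcode → subject.  Subjects with no cells of a type are left NaN (to be
    imputed from training subjects downstream).
    """
    subjects = pd.Index(labels.index)
    sig = de[de["significant"]]
    cols: dict[str, pd.Series] = {}
    for (ct, mod), rows in sig.groupby(["cell_type", "modality"], observed=True):
        key = (ct, mod)
        if key not in scaled_expr:
            raise ValueError(f"no expression available for {ct} / {mod}")
        expr = scaled_expr[key]
        if hasattr(expr, "to_frame") and not isinstance(expr, pd.DataFrame):
            expr = expr.to_frame()
        missing = [f for f in rows["feature"] if f not in expr.columns]
        if missing:
            raise ValueError(
                f"DE features absent from {ct}/{mod} expression: {missing[:5]}")
        subj = cell_subjects.reindex(expr.index)
        means = expr[list(dict.fromkeys(rows["feature"]))].groupby(
            subj.to_numpy(), observed=True).mean()
        means = means.reindex(subjects)
        for f in means.columns:
            cols[feature_id(ct, mod, f)] = means[f]
    values = pd.DataFrame(cols, index=subjects)
    return SubjectFeatureMatrix(values, labels.reindex(subjects),
                                provenance=provenance)


def build_profile_matrix(rna, adt, de: pd.DataFrame, labels: pd.Series,
                         rna_scale: float = 1e7, adt_scale: float = 5e5
                         ) -> SubjectFeatureMatrix:
    """Alternative feature-matrix provenance: within-subject log profiles.

    For each significant DE feature, the value is
    ln(feature counts / total counts × scale) over the subject's cells of
    that cell type, aggregating raw counts only within each subject —
    no across-subject fitting, which is the point of this provenance as a
    leakage check on the scaled-mean pipeline.
    """
    from .normalize import subject_profile

    subjects = pd.Index(labels.index)
    sig = de[de["significant"]]
    cols: dict[str, pd.Series] = {}
    for (ct, mod), rows in sig.groupby(["cell_type", "modality"], observed=True):
        adata = rna if mod == "RNA" else adt
        if adata is None:
            raise ValueError(f"no {mod} matrix available for {ct}")
        mask = (adata.obs["cell_type"].astype(str) == ct).to_numpy()
        sub = adata[mask]
        feats = [f for f in dict.fromkeys(rows["feature"])]
        missing = [f for f in feats if f not in sub.var_names]
        if missing:
            raise ValueError(f"DE features absent from {ct}/{mod}: {missing[:5]}")
        prof = subject_profile(sub, sub.obs["subject"].astype(str),
                               rna_scale if mod == "RNA" else adt_scale)
        vals = prof.values.reindex(subjects)
        for f in feats:
            cols[feature_id(ct, mod, f)] = vals[f]
    return SubjectFeatureMatrix(pd.DataFrame(cols, index=subjects),
                                labels.reindex(subjects),
                                provenance="subject-logcpm")


def impute_missing(m: SubjectFeatureMatrix, train_subjects: pd.Index
                   ) -> SubjectFeatureMatrix:
    """Fill missing subject × feature values with the training-cohort mean
    of that feature; records the imputation mask."""
    fill = m.values.loc[train_subjects].mean(axis=0)
    mask = m.values.isna()
    values = m.values.fillna(fill)
    if values.isna().any().any():
        raise ValueError("features with no observed training values")
    return SubjectFeatureMatrix(values, m.labels, m.provenance, imputed=mask)


def stratified_split(labels: pd.Series, seed: int,
                     train_fraction: float = 0.5
                     ) -> tuple[pd.Index, pd.Index]:
    """Per class, assign ceil(n × fraction) subjects to training and the
    rest to test, membership randomized by the seed."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(labels.unique()):
        ids = np.sort(labels.index[labels == cls].to_numpy())
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 subjects")
        perm = rng.permutation(len(ids))
        n_train = int(np.ceil(len(ids) * train_fraction))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return pd.Index(sorted(train)), pd.Index(sorted(test))


# --------------------------------------------------------------------------
# ensemble feature selection
# --------------------------------------------------------------------------

def _cv_accuracy(X: np.ndarray, y: np.ndarray, cols: list[int], seed: int) -> float:
    est = LogisticRegression(max_iter=1000)
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(cross_val_score(est, X[:, cols], y, cv=cv,
                                     scoring="accuracy").mean())


def _selector_stepwise(X: np.ndarray, y: np.ndarray, names: list[str],
                       seed: int) -> pd.Series:
    """Forward and backward stepwise selection with a logistic model;
    importance decreases with the step at which a feature enters (forward)
    or leaves (backward)."""
    d = X.shape[1]
    cap = min(d, 40)  # stepwise over the univariately strongest features
    if d > cap:
        t = np.abs((X[y == 1].mean(0) - X[y == 0].mean(0))
                   / (X.std(0, ddof=1) + 1e-12))
        pool = list(np.argsort(-t, kind="stable")[:cap])
    else:
        pool = list(range(d))
    m = min(len(pool), 20)

    fwd_rank = np.zeros(d)
    chosen: list[int] = []
    remaining = list(pool)
    for step in range(m):
        scores = [( _cv_accuracy(X, y, chosen + [f], seed), -f) for f in remaining]
        best = remaining[int(np.argmax([s for s, _ in scores]))]
        chosen.append(best)
        remaining.remove(best)
        fwd_rank[best] = m - step
    bwd_rank = np.zeros(d)
    alive = list(pool)
    step = 0
    while len(alive) > 1:
        scores = [_cv_accuracy(X, y, [g for g in alive if g != f], seed)
                  for f in alive]
        worst = alive[int(np.argmax(scores))]
        alive.remove(worst)
        bwd_rank[worst] = step + 1
        step += 1
    bwd_rank[alive[0]] = step + 1
    imp = fwd_rank / max(fwd_rank.sum(), 1e-12) + bwd_rank / max(bwd_rank.sum(), 1e-12)
    return pd.Series(imp / 2.0, index=names)


def _selector_rfe_rf(X, y, names, seed) -> pd.Series:
    rf = RandomForestClassifier(n_estimators=50, random_state=seed)
    rfe = RFE(rf, n_features_to_select=1, step=1)
    rfe.fit(X, y)
    imp = (len(names) - rfe.ranking_ + 1).astype(float)
    return pd.Series(imp / imp.sum(), index=names)


def _perm_importance(est, X, y, names, seed) -> pd.Series:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
        # a continuous score keeps importances graded at small n, where
        # accuracy would tie across most permutations
        r = permutation_importance(est, X, y, n_repeats=10, random_state=seed,
                                   scoring="roc_auc")
    imp = np.clip(r.importances_mean, 0.0, None)
    total = imp.sum()
    if total <= 0:
        raise RuntimeError("flat permutation importance")
    return pd.Series(imp / total, index=names)


def _selector_svm(X, y, names, seed) -> pd.Series:
    return _perm_importance(SVC(kernel="rbf", C=1.0), X, y, names, seed)


def _selector_nnet(X, y, names, seed) -> pd.Series:
    est = MLPClassifier(hidden_layer_sizes=(5,), alpha=1e-2, max_iter=2000,
                        random_state=seed)
    return _perm_importance(est, X, y, names, seed)


SELECTORS = {
    "stepwise": _selector_stepwise,
    "rfe_rf": _selector_rfe_rf,
    "svm_radial": _selector_svm,
    "nnet": _selector_nnet,
}


def ensemble_select(X: pd.DataFrame, y: pd.Series, n_top: int, seed: int,
                    selectors: dict | None = None) -> SelectionResult:
    """Ensemble feature selection.

    Each selector emits a per-feature importance normalized to sum to one
    (features it discards get 0); the aggregate score is the mean of the
    normalized importances, ties broken lexicographically by feature id.
    A selector that fails on degenerate input is dropped with a warning.
    """
    if n_top > X.shape[1]:
        raise ValueError(f"n_top={n_top} exceeds {X.shape[1]} features")
    selectors = selectors or SELECTORS
    names = list(X.columns)
    scaler = StandardScaler().fit(X.to_numpy())
    Xs = scaler.transform(X.to_numpy())
    yv = y.reindex(X.index).to_numpy()
    yb = (yv == sorted(set(yv))[0]).astype(int) if yv.dtype == object else yv
    cols = {}
    for i, (name, fn) in enumerate(selectors.items()):
        try:
            cols[name] = fn(Xs, yb, names, seed + i)
        except Exception as e:  # degenerate input for this selector
            warnings.warn(f"selector {name!r} failed ({e}); dropped")
    if not cols:
        raise RuntimeError("every selector failed")
    table = pd.DataFrame(cols).fillna(0.0)
    table["aggregate"] = table.mean(axis=1)
    # deterministic tie-break: sort by (-aggregate, feature id)
    order = sorted(table.index, key=lambda f: (-table.at[f, "aggregate"], f))
    table = table.loc[order]
    return SelectionResult(table, list(table.index[:n_top]), n_top)


# --------------------------------------------------------------------------
# model roster
# --------------------------------------------------------------------------

def get_roster(names: tuple[str, ...], seed: int) -> dict[str, tuple]:
    """Estimators and tuning grids for the model roster.

    Nine families spanning linear (regularized logistic regression, LDA,
    elastic net), non-linear (kNN, decision tree, radial SVM, naive Bayes,
    averaged small neural nets) and ensemble (random forest) models.
    """
    def pipe(est):
        return Pipeline([("scale", StandardScaler()), ("model", est)])

    defs = {
        "glm": (pipe(LogisticRegression(max_iter=5000)),
                {"model__C": [0.01, 0.1, 1.0, 10.0]}),
        "lda": (pipe(LinearDiscriminantAnalysis()), {}),
        "glmnet": (pipe(LogisticRegression(penalty="elasticnet", solver="saga",
                                           max_iter=5000)),
                   {"model__C": [0.1, 1.0], "model__l1_ratio": [0.1, 0.5, 0.9]}),
        "knn": (pipe(KNeighborsClassifier()),
                {"model__n_neighbors": [3, 5, 7]}),
        "cart": (pipe(DecisionTreeClassifier(random_state=seed)),
                 {"model__max_depth": [2, 3, 5, None],
                  "model__min_samples_leaf": [1, 2, 5]}),
        "rf": (pipe(RandomForestClassifier(n_estimators=20, max_features="sqrt",
                                           random_state=seed)),
               {"model__max_depth": [50, 80, 100, 150, 300],
                "model__min_impurity_decrease": [0.0, 0.02, 0.1, 0.5],
                "model__min_samples_leaf": [1, 2, 5, 10]}),
        "gbm": (pipe(GradientBoostingClassifier(random_state=seed)),
                {"model__n_estimators": [20, 50],
                 "model__max_depth": [1, 2, 3]}),
        "svmRadial": (pipe(SVC(kernel="rbf", probability=True,
                               random_state=seed)),
                      {"model__C": [0.25, 0.5, 1.0, 2.0, 4.0],
                       "model__gamma": ["scale", 0.01, 0.1]}),
        "nb": (pipe(GaussianNB()),
               {"model__var_smoothing": [1e-9, 1e-6, 1e-3]}),
        "avNNet": (pipe(BaggingClassifier(
                        MLPClassifier(solver="lbfgs", max_iter=500,
                                      random_state=seed),
                        n_estimators=3, random_state=seed)),
                   {"model__estimator__hidden_layer_sizes": [(1,), (3,), (5,)],
                    "model__estimator__alpha": [1e-2, 1e-1]}),
    }
    unknown = [n for n in names if n not in defs]
    if unknown:
        raise ValueError(f"unknown roster models: {unknown}")
    return {n: defs[n] for n in names}


def train_models(X: pd.DataFrame, y: pd.Series, roster: dict[str, tuple],
                 folds: int = 5, repeats: int = 2, seed: int = 0,
                 positive: str = "AS") -> dict[str, dict]:
    """Tune and fit each roster model with repeated stratified CV.

    Returns per model the refitted estimator, the CV accuracy/kappa of the
    selected hyperparameters (mean and sd over folds), and the chosen
    parameters.
    """
    yv = y.reindex(X.index)
    yb = (yv == positive).astype(int).to_numpy()
    counts = np.bincount(yb, minlength=2)
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
        warnings.warn(f"class too small for requested folds; using {folds}")
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    scoring = {"accuracy": "accuracy",
               "kappa": make_scorer(cohen_kappa_score)}
    out = {}
    for name, (est, grid) in roster.items():
        gs = GridSearchCV(clone(est), grid or {}, scoring=scoring,
                          refit="accuracy", cv=cv, n_jobs=None,
                          error_score=np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs.fit(X.to_numpy(), yb)
        i = gs.best_index_
        out[name] = {
            "model": gs.best_estimator_,
            "best_params": gs.best_params_,
            "cv_accuracy_mean": float(gs.cv_results_["mean_test_accuracy"][i]),
            "cv_accuracy_sd": float(gs.cv_results_["std_test_accuracy"][i]),
            "cv_kappa_mean": float(gs.cv_results_["mean_test_kappa"][i]),
            "cv_kappa_sd": float(gs.cv_results_["std_test_kappa"][i]),
            "cv_scheme": f"{folds}-fold x {repeats}",
        }
    return out


# --------------------------------------------------------------------------
# evaluation metrics (own implementations; AUROC by pairwise concordance)
# --------------------------------------------------------------------------

def auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUROC as the fraction of (positive, negative) pairs in which the
    positive outscores the negative; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    pos = scores[y]
    neg = scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes to compute AUROC")
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def cohen_kappa(tp: int, fn: int, fp: int, tn: int) -> float:
    n = tp + fn + fp + tn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n ** 2
    if pe == 1.0:
        return 0.0
    return (po - pe) / (1 - pe)


def _roc_points(scores: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    order = np.argsort(-scores, kind="stable")
    y = np.asarray(y).astype(bool)[order]
    P, N = int(y.sum()), int((~y).sum())
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i, is_pos in enumerate(y):
        if is_pos:
            tp += 1
        else:
            fp += 1
        if i + 1 < len(y) and scores[order[i + 1]] == scores[order[i]]:
            continue
        pts.append((fp / N if N else 0.0, tp / P if P else 0.0))
    return pts


def evaluate_models(models: dict[str, dict], X_test: pd.DataFrame,
                    y_test: pd.Series, positive: str = "AS") -> dict[str, dict]:
    """Held-out evaluation.  Scores come from predict_proba when available,
    otherwise from decision values (noted in the report); the confusion
    matrix uses a 0.5 probability (or 0 decision) threshold."""
    yb = (y_test.reindex(X_test.index) == positive).astype(int).to_numpy()
    report = {}
    for name, entry in models.items():
        est = entry["model"]
        note = ""
        if hasattr(est, "predict_proba"):
            scores = est.predict_proba(X_test.to_numpy())[:, 1]
            thresh = 0.5
        else:
            scores = est.decision_function(X_test.to_numpy())
            thresh = 0.0
            note = "scores from decision values"
        pred = (scores > thresh).astype(int)
        tp = int(((pred == 1) & (yb == 1)).sum())
        fn = int(((pred == 0) & (yb == 1)).sum())
        fp = int(((pred == 1) & (yb == 0)).sum())
        tn = int(((pred == 0) & (yb == 0)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
        report[name] = {
            **{k: v for k, v in entry.items() if k != "model"},
            "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
            "accuracy": (tp + tn) / len(yb),
            "sensitivity": sens, "specificity": spec, "f1": f1,
            "kappa": cohen_kappa(tp, fn, fp, tn),
            "auroc": auroc(scores, yb),
            "roc_points": _roc_points(scores, yb),
            "note": note,
        }
    return report


def run_ml(m: SubjectFeatureMatrix, *, n_top: int = 20, seed: int = 0,
           roster_names: tuple[str, ...] = ("glm", "lda", "glmnet", "knn",
                                            "cart", "rf", "svmRadial", "nb",
                                            "avNNet"),
           folds: int = 5, repeats: int = 2, positive: str = "AS",
           train_fraction: float = 0.5) -> dict:
    """Split → impute → select → train → evaluate, end to end."""
    train_ids, test_ids = stratified_split(m.labels, seed, train_fraction)
    filled = impute_missing(m, train_ids)
    X_train = filled.values.loc[train_ids]
    X_test = filled.values.loc[test_ids]
    n_top = min(n_top, X_train.shape[1])
    sel = ensemble_select(X_train, m.labels.loc[train_ids], n_top, seed)
    roster = get_roster(roster_names, seed)
    models = train_models(X_train[sel.selected], m.labels, roster,
                          folds=folds, repeats=repeats, seed=seed,
                          positive=positive)
    report = evaluate_models(models, X_test[sel.selected],
                             m.labels, positive=positive)
    best = max(report, key=lambda k: report[k]["auroc"])
    return {"train_subjects": list(train_ids), "test_subjects": list(test_ids),
            "selected_features": sel.selected,
            "selection_table": sel.table,
            "models": models, "report": report, "best_model": best,
            "best_auroc": report[best]["auroc"]}
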