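"""Cell-type-scoped differential expression.

Genes are tested with a per-gene negative-binomial log-linear regression of
(corrected) counts on the cohort indicator plus log10 total counts and
log10 detected features, with per-gene maximum-likelihood dispersion
(method-of-moments fallback) and a two-sided Wald test on the cohort
coefficient.  Surface proteins are tested with the Wilcoxon rank-sum test
on centered/scaled CLR values.  Both are Bonferroni-adjusted within the
tested family (one cell type × modality) and gated on effect size:
|log2 fold change| >= 0.20 for genes (fold change of group means with a
pseudo-mean of 1), |mean scaled difference| >= 0.20 for proteins.

A batch-artifact filter removes hits driven by a single sequencing batch:
a result is flagged when re-testing without the batch with the highest mean
expression of that feature loses either the effect-size gate or adjusted
significance.

The NB fitting is a batched IRLS across genes (the design matrix is shared,
per-gene weighted normal equations are solved in a stacked linear solve),
alternating with Newton updates of the per-gene dispersion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special, stats

from .composition import rank_sum_test

__all__ = ["nb_glm_fit", "de_genes", "de_proteins", "flag_batch_artifacts"]

DE_COLUMNS = ["feature", "cell_type", "modality", "effect", "p", "p_adj",
              "significant", "artifact_flag", "artifact_reason", "n_tested"]


# --------------------------------------------------------------------------
# batched negative-binomial GLM
# --------------------------------------------------------------------------

def _irls(Y: np.ndarray, X: np.ndarray, beta: np.ndarray,
          theta: np.ndarray | None, n_iter: int, tol: float = 1e-6
          ) -> np.ndarray:
    """Batched IRLS for log-link Poisson (theta None) or NB regression.

    Y: cells × genes, X: cells × p, beta: p × genes.  Returns updated beta.
    """
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        if theta is None:
            w = mu
        else:
            w = mu / (1.0 + mu / theta[None, :])
        z = eta + (Y - mu) / np.maximum(mu, 1e-12)
        A = np.einsum("ni,ng,nj->gij", X, w, X)
        b = np.einsum("ni,ng->gi", X, w * z)
        A += 1e-10 * np.eye(X.shape[1])[None, :, :]
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0].T  # p × genes
        except np.linalg.LinAlgError:
            new = np.stack([np.linalg.lstsq(A[g], b[g], rcond=None)[0]
                            for g in range(Y.shape[1])], axis=1)
        delta = np.max(np.abs(new - beta))
        beta = new
        if delta < tol:
            break
    return beta


def _theta_mom(Y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    num = (mu ** 2).sum(axis=0)
    den = ((Y - mu) ** 2 - mu).sum(axis=0)
    th = np.where(den > 0, num / np.maximum(den, 1e-12), 1e6)
    return np.clip(th, 1e-2, 1e6)


def _theta_ml(Y: np.ndarray, mu: np.ndarray, theta0: np.ndarray,
              n_iter: int = 8) -> np.ndarray:
    """Per-gene ML dispersion given fitted means, by Newton on log(theta)."""
    lt = np.log(theta0)
    for _ in range(n_iter):
        th = np.exp(lt)[None, :]
        grad = (special.digamma(Y + th) - special.digamma(th)
                + np.log(th) + 1.0 - np.log(th + mu)
                - (Y + th) / (th + mu)).sum(axis=0) * np.exp(lt)
        hess_t = (special.polygamma(1, Y + th) - special.polygamma(1, th)
                  + 1.0 / th - 2.0 / (th + mu)
                  + (Y + th) / (th + mu) ** 2).sum(axis=0)
        hess = hess_t * np.exp(lt) ** 2 + grad  # chain rule onto log scale
        step = np.where(hess < 0, grad / hess, -np.sign(grad) * 0.5)
        step = np.clip(step, -2.0, 2.0)
        lt = np.clip(lt - step, np.log(1e-2), np.log(1e6))
        if np.max(np.abs(step)) < 1e-6:
            break
    return np.exp(lt)


def nb_glm_fit(Y: np.ndarray, X: np.ndarray, n_outer: int = 2
               ) -> dict[str, np.ndarray]:
    """Fit per-gene NB GLMs with a shared design matrix.

    Returns beta (p × genes), se (p × genes), theta (genes).  Dispersion is
    estimated by ML (Newton, method-of-moments start and fallback),
    alternating with IRLS coefficient updates.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n, g = Y.shape
    beta = np.zeros((X.shape[1], g))
    beta[0] = np.log(np.maximum(Y.mean(axis=0), 1e-8))
    beta = _irls(Y, X, beta, None, n_iter=15)  # Poisson start
    mu = np.exp(np.clip(X @ beta, -30, 30))
    theta = _theta_mom(Y, mu)
    for _ in range(n_outer):
        with np.errstate(all="ignore"):
            theta_new = _theta_ml(Y, mu, theta)
        bad = ~np.isfinite(theta_new)
        theta = np.where(bad, theta, theta_new)
        beta = _irls(Y, X, beta, theta, n_iter=12)
        mu = np.exp(np.clip(X @ beta, -30, 30))
    w = mu / (1.0 + mu / theta[None, :])
    A = np.einsum("ni,ng,nj->gij", X, w, X)
    A += 1e-10 * np.eye(X.shape[1])[None, :, :]
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0)).T
    return {"beta": beta, "se": se, "theta": theta}


# --------------------------------------------------------------------------
# DE operations
# --------------------------------------------------------------------------

def _as_matrix(counts) -> tuple[np.ndarray, pd.Index, pd.Index]:
    import anndata as ad

    if isinstance(counts, ad.AnnData):
        X = counts.X
        X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
        return X.astype(np.float64), counts.obs_names.copy(), counts.var_names.copy()
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=np.float64), counts.index, counts.columns
    X = np.asarray(counts, dtype=np.float64)
    return X, pd.RangeIndex(X.shape[0]), pd.Index([f"f{i}" for i in range(X.shape[1])])


def _check_groups(labels: np.ndarray, group: str, reference: str,
                  min_cells: int) -> tuple[np.ndarray, np.ndarray]:
    ga = labels == group
    gb = labels == reference
    if not ga.any() or not gb.any():
        raise ValueError(
            f"need cells in both groups ({group!r} vs {reference!r}); "
            f"labels present: {sorted(set(labels))}")
    if ga.sum() < min_cells or gb.sum() < min_cells:
        raise ValueError(
            f"fewer than {min_cells} cells in a group "
            f"({group}: {ga.sum()}, {reference}: {gb.sum()})")
    return ga, gb


def de_genes(counts, groups, *, group: str = "AS", reference: str = "healthy",
             covariates: pd.DataFrame | None = None, alpha: float = 0.05,
             min_lfc: float = 0.20, min_cells: int = 3,
             cell_type: str = "") -> pd.DataFrame:
    """NB differential test per gene between two cell groups.

    ``counts`` should be corrected (or raw) counts for the cells of one
    cell type.  ``groups`` is a per-cell label array/Series.  Effect size is
    log2((mean_group + 1) / (mean_reference + 1)) on group means of the
    input counts; Bonferroni is over the genes tested here.
    """
    Y, cells, features = _as_matrix(counts)
    labels = np.asarray(pd.Series(groups).reindex(cells)
                        if isinstance(groups, pd.Series) else groups)
    ga, gb = _check_groups(labels, group, reference, min_cells)
    keep_cells = ga | gb
    Y = Y[keep_cells]
    ga, gb = ga[keep_cells], gb[keep_cells]

    tested = (Y[ga].sum(axis=0) + Y[gb].sum(axis=0)) > 0
    n_tested = int(tested.sum())
    out = pd.DataFrame({
        "feature": features, "cell_type": cell_type, "modality": "RNA",
        "effect": np.nan, "p": np.nan, "p_adj": np.nan,
        "significant": False, "artifact_flag": False, "artifact_reason": "",
        "n_tested": n_tested})
    if n_tested == 0:
        return out[tested.tolist()].reset_index(drop=True)

    Yt = Y[:, tested]
    if covariates is None:
        totals = Y.sum(axis=1)
        nfeat = (Y > 0).sum(axis=1)
        C = np.column_stack([np.log10(np.maximum(totals, 1)),
                             np.log10(np.maximum(nfeat, 1))])
    else:
        C = covariates.loc[cells[keep_cells]].to_numpy(dtype=float) \
            if isinstance(covariates, pd.DataFrame) else np.asarray(covariates)[keep_cells]
    cov_cols = [c for c in range(C.shape[1]) if np.ptp(C[:, c]) > 0]
    X = np.column_stack([np.ones(Yt.shape[0]), ga.astype(float)]
                        + [C[:, c] for c in cov_cols])

    fit = nb_glm_fit(Yt, X)
    z = fit["beta"][1] / np.maximum(fit["se"][1], 1e-12)
    p = 2.0 * stats.norm.sf(np.abs(z))
    mean_a = Yt[ga].mean(axis=0)
    mean_b = Yt[gb].mean(axis=0)
    effect = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    p_adj = np.minimum(p * n_tested, 1.0)

    out = out[tested.tolist()].reset_index(drop=True)
    out["effect"] = effect
    out["p"] = p
    out["p_adj"] = p_adj
    out["significant"] = (p_adj < alpha) & (np.abs(effect) >= min_lfc)
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def de_proteins(scaled, groups, *, group: str = "AS",
                reference: str = "healthy", alpha: float = 0.05,
                min_diff: float = 0.20, min_cells: int = 3,
                cell_type: str = "") -> pd.DataFrame:
    """Wilcoxon rank-sum per tag on centered/scaled CLR values.

    ``scaled`` is a cells × tags matrix (NormalizedMatrix, DataFrame or
    array) restricted to cells with measured ADT data.  Effect size is the
    difference of group means of the scaled values.
    """
    from .normalize import NormalizedMatrix

    if isinstance(scaled, NormalizedMatrix):
        V, cells, features = scaled.values, scaled.cells, scaled.features
    else:
        V, cells, features = _as_matrix(scaled)
    labels = np.asarray(pd.Series(groups).reindex(cells)
                        if isinstance(groups, pd.Series) else groups)
    ga, gb = _check_groups(labels, group, reference, min_cells)
    A, B = V[ga], V[gb]
    n_tested = V.shape[1]
    if min(A.shape[0], B.shape[0]) > 10:
        res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                 method="asymptotic", axis=0)
        stat = np.asarray(res.statistic, dtype=float)
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    else:
        stat = np.empty(n_tested)
        p = np.empty(n_tested)
        for j in range(n_tested):
            stat[j], p[j] = rank_sum_test(A[:, j], B[:, j])
    effect = A.mean(axis=0) - B.mean(axis=0)
    p_adj = np.minimum(p * n_tested, 1.0)
    out = pd.DataFrame({
        "feature": features, "cell_type": cell_type, "modality": "ADT",
        "effect": effect, "p": p, "p_adj": p_adj,
        "significant": (p_adj < alpha) & (np.abs(effect) >= min_diff),
        "artifact_flag": False, "artifact_reason": "",
        "n_tested": n_tested})
    return out.sort_values("p_adj", kind="stable").reset_index(drop=True)


def flag_batch_artifacts(results: pd.DataFrame, expr, groups, batches, *,
                         group: str = "AS", reference: str = "healthy",
                         alpha: float = 0.05, min_effect: float = 0.20
                         ) -> pd.DataFrame:
    """Flag significant results not robust to removing their dominant batch.

    For each significant feature, the batch with the highest mean expression
    is dropped and the feature is re-tested on the remaining cells (same
    test family, adjusted with the original family size).  If the refit
    loses the effect gate or adjusted significance, the result is flagged
    and ``significant`` is withdrawn.
    """
    if results.empty:
        return results.copy()
    V, cells, features = _as_matrix(expr)
    labels = np.asarray(pd.Series(groups).reindex(cells)
                        if isinstance(groups, pd.Series) else groups)
    bvec = np.asarray(pd.Series(batches).reindex(cells)
                      if isinstance(batches, pd.Series) else batches)
    uniq_b = np.unique(bvec)
    out = results.copy().reset_index(drop=True)
    if len(uniq_b) < 2:
        warnings.warn("single batch; artifact filtering is a no-op")
        return out
    fidx = {f: j for j, f in enumerate(features)}
    modality = out["modality"].iloc[0] if len(out) else "RNA"

    for i, row in out.iterrows():
        if not row["significant"]:
            continue
        j = fidx.get(row["feature"])
        if j is None:
            continue
        col = V[:, j]
        bmeans = {b: col[bvec == b].mean() for b in uniq_b}
        dominant = max(bmeans, key=lambda b: (bmeans[b], str(b)))
        keep = bvec != dominant
        sub = col[keep]
        lab = labels[keep]
        ga = lab == group
        gb = lab == reference
        if ga.sum() < 3 or gb.sum() < 3:
            continue
        n_tested = int(row["n_tested"])
        if modality == "RNA":
            totals = V[keep].sum(axis=1)
            nfeat = (V[keep] > 0).sum(axis=1)
            X = np.column_stack([np.ones(keep.sum()), ga.astype(float),
                                 np.log10(np.maximum(totals, 1)),
                                 np.log10(np.maximum(nfeat, 1))])
            fit = nb_glm_fit(sub[:, None], X)
            z = fit["beta"][1, 0] / max(fit["se"][1, 0], 1e-12)
            p_new = 2.0 * stats.norm.sf(abs(z))
            eff_new = np.log2((sub[ga].mean() + 1.0) / (sub[gb].mean() + 1.0))
        else:
            _, p_new = rank_sum_test(sub[ga], sub[gb])
            eff_new = sub[ga].mean() - sub[gb].mean()
        p_adj_new = min(p_new * n_tested, 1.0)
        if abs(eff_new) < min_effect or p_adj_new >= alpha:
            out.at[i, "artifact_flag"] = True
            out.at[i, "artifact_reason"] = f"dominant batch {dominant}"
            out.at[i, "significant"] = False
    return out
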