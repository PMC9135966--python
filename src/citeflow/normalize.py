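"""Normalization of CITE-seq count data.

Three normalizations are used downstream:

* **Pearson-residual variance stabilization** for RNA (``vst_residuals``):
  per gene, a negative-binomial regression of counts on log10 total cell
  UMIs; raw per-gene dispersions are regularized by Gaussian-kernel
  smoothing against log10 gene mean (Silverman bandwidth); the output is
  the Pearson residual (x - mu) / sqrt(mu + mu^2/theta), clipped to
  +/- sqrt(n_cells).  "Corrected counts" — expected counts at the median
  library size, de-noised through the residuals — are also produced for
  the count-based differential test.

* **Centered log-ratio (CLR)** for ADT (``clr_normalize``): per cell,
  ln(x+1) minus the cell's mean of ln(x+1) across tags — the classic CLR
  on pseudocounted counts, applied across features within each cell.

* **Subject-level log profile** (``subject_profile``): for each subject,
  ln(feature counts / total counts x scaling factor), with the scaling
  factor near the maximum per-subject total (1e7 for RNA, 5e5 for ADT).

Helper transforms: per-feature OLS covariate regression
(``regress_covariates``) and per-feature centering/unit scaling
(``center_scale``, n-1 denominator, zero-variance features map to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

__all__ = ["NormalizedMatrix", "clr_normalize", "vst_residuals",
           "regress_covariates", "center_scale", "subject_profile",
           "SubjectProfile"]


@dataclass
class NormalizedMatrix:
    """Dense normalized values (cells × features) with provenance."""

    values: np.ndarray
    cells: pd.Index
    features: pd.Index
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells, columns=self.features)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cells), len(self.features)):
            raise ValueError("values shape does not match cell/feature axes")


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def clr_normalize(adt: ad.AnnData, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Centered log-ratio per cell: ln(x+c) − mean_g ln(x+c)."""
    if adt.n_vars == 0:
        raise ValueError("CLR on an empty feature axis")
    L = np.log(_dense(adt.X) + pseudocount)
    L -= L.mean(axis=1, keepdims=True)
    return NormalizedMatrix(L, adt.obs_names.copy(), adt.var_names.copy(),
                            "clr", {"pseudocount": pseudocount})


# --------------------------------------------------------------------------
# variance-stabilizing transformation (regularized NB Pearson residuals)
# --------------------------------------------------------------------------

def _poisson_irls(Y: np.ndarray, x: np.ndarray, n_iter: int = 30,
                  tol: float = 1e-8) -> np.ndarray:
    """Per-gene Poisson regression log mu = b0 + b1 * x, vectorized over
    genes.  Y is cells × genes; x is the per-cell predictor.  Returns
    beta (2 × genes)."""
    n, g = Y.shape
    X = np.column_stack([np.ones(n), x])
    ybar = Y.mean(axis=0)
    beta = np.vstack([np.log(np.maximum(ybar, 1e-8)), np.zeros(g)])
    for _ in range(n_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        z = eta + (Y - mu) / mu
        # weighted normal equations per gene, 2x2 closed form
        w = mu
        s0 = w.sum(axis=0)
        s1 = (w * x[:, None]).sum(axis=0)
        s2 = (w * (x ** 2)[:, None]).sum(axis=0)
        t0 = (w * z).sum(axis=0)
        t1 = (w * z * x[:, None]).sum(axis=0)
        det = s0 * s2 - s1 ** 2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        b0 = (s2 * t0 - s1 * t1) / det
        b1 = (s0 * t1 - s1 * t0) / det
        new = np.vstack([b0, b1])
        if np.nanmax(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    if n < 2:
        return 1.0
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        return 1.0
    return 0.9 * spread * n ** (-0.2)


def _kernel_smooth(x: np.ndarray, y: np.ndarray, bw: float) -> np.ndarray:
    """Nadaraya–Watson smoothing of y against x with a Gaussian kernel."""
    d = (x[:, None] - x[None, :]) / bw
    K = np.exp(-0.5 * d ** 2)
    return (K @ y) / K.sum(axis=1)


def vst_residuals(rna: ad.AnnData, clip: float | None = None,
                  regularize: bool = True) -> NormalizedMatrix:
    """Regularized NB Pearson residuals of RNA counts against log10 library
    size, with corrected counts in ``params['corrected_counts']``."""
    if rna.n_obs < 2:
        raise ValueError("VST needs at least 2 cells")
    Y = _dense(rna.X)
    n, g = Y.shape
    totals = Y.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts; run QC first")
    x = np.log10(totals)
    nonzero = Y.sum(axis=0) > 0

    beta = np.zeros((2, g))
    theta = np.full(g, np.inf)
    if nonzero.any():
        Yn = Y[:, nonzero]
        b = _poisson_irls(Yn, x)
        mu = np.exp(np.clip(np.column_stack([np.ones(n), x]) @ b, -30, 30))
        # method-of-moments dispersion: Var = mu + mu^2/theta
        num = (mu ** 2).sum(axis=0)
        den = ((Yn - mu) ** 2 - mu).sum(axis=0)
        th_raw = np.where(den > 0, num / np.maximum(den, 1e-12), 1e6)
        th_raw = np.clip(th_raw, 1e-3, 1e6)
        if regularize and nonzero.sum() > 1:
            lm = np.log10(np.maximum(Yn.mean(axis=0), 1e-8))
            bw = _silverman_bandwidth(lm)
            th_s = 10 ** _kernel_smooth(lm, np.log10(th_raw), bw)
        else:
            th_s = th_raw
        beta[:, nonzero] = b
        theta[nonzero] = th_s

    eta = np.column_stack([np.ones(n), x]) @ beta
    mu = np.where(nonzero[None, :], np.exp(np.clip(eta, -30, 30)), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.sqrt(mu + mu ** 2 / theta[None, :])
        resid = np.where(sd > 0, (Y - mu) / sd, 0.0)
    bound = clip if clip is not None else np.sqrt(n)
    resid = np.clip(resid, -bound, bound)

    # corrected counts: expected counts at the median library size,
    # reconstructed from the clipped residuals
    x_med = np.median(x)
    mu_med = np.where(nonzero[None, :],
                      np.exp(np.clip(beta[0] + beta[1] * x_med, -30, 30))[None, :]
                      * np.ones((n, 1)), 0.0)
    sd_med = np.sqrt(mu_med + mu_med ** 2 / theta[None, :])
    corrected = np.rint(np.maximum(mu_med + resid * np.where(np.isfinite(sd_med), sd_med, 0.0), 0.0)).astype(np.int64)

    return NormalizedMatrix(
        resid, rna.obs_names.copy(), rna.var_names.copy(), "pearson_residual",
        {"clip": float(bound), "theta": theta, "beta": beta,
         "regularized": regularize,
         "corrected_counts": corrected})


def regress_covariates(m: NormalizedMatrix, covariates: pd.DataFrame
                       ) -> NormalizedMatrix:
    """Replace each feature by its residual from an OLS fit on the given
    per-cell covariates (with intercept).  Constant covariates are dropped
    with a warning rather than crashing the normal equations."""
    import warnings

    if len(covariates) != len(m.cells):
        raise ValueError("covariates do not align with cells")
    cov = covariates.loc[m.cells] if not covariates.index.equals(m.cells) \
        else covariates
    cols = []
    names = []
    for c in cov.columns:
        v = cov[c].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {c!r} is constant; dropped")
            continue
        cols.append(v)
        names.append(c)
    X = np.column_stack([np.ones(len(m.cells))] + cols)
    coef, *_ = np.linalg.lstsq(X, m.values, rcond=None)
    resid = m.values - X @ coef
    return NormalizedMatrix(resid, m.cells, m.features, m.method,
                            {**m.params, "regressed": names})


def center_scale(m: NormalizedMatrix) -> NormalizedMatrix:
    """Per-feature mean-centering and unit scaling (n−1 denominator);
    zero-variance features map to 0."""
    v = m.values - m.values.mean(axis=0, keepdims=True)
    sd = m.values.std(axis=0, ddof=1) if len(m.cells) > 1 else np.zeros(len(m.features))
    out = np.where(sd > 0, v / np.where(sd > 0, sd, 1.0), 0.0)
    return NormalizedMatrix(out, m.cells, m.features, "scaled",
                            {**m.params, "scaled": True})


# --------------------------------------------------------------------------
# subject-level log profile
# --------------------------------------------------------------------------

@dataclass
class SubjectProfile:
    values: pd.DataFrame  # subjects × features
    scaling_factor: float
    zero_policy: str


def subject_profile(counts: ad.AnnData, subjects: pd.Series,
                    scaling_factor: float,
                    zero_pseudocount: float = 1.0) -> SubjectProfile:
    """Per-subject profile: ln(feature counts / subject total × factor).

    Counts are summed over each subject's cells; a pseudocount is added to
    zero feature sums only, so values for nonzero counts follow the formula
    exactly.  Depends only on per-subject sums, so it is invariant to how
    cells are partitioned into batches.
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be positive")
    subjects = subjects.loc[counts.obs_names]
    X = counts.X.tocsr()
    groups = pd.Index(subjects.unique())
    rows = []
    for s in groups:
        mask = (subjects == s).to_numpy()
        sums = np.asarray(X[mask].sum(axis=0)).ravel()
        total = sums.sum()
        if total <= 0:
            raise ValueError(f"subject {s!r} has zero total counts")
        sums = np.where(sums == 0, zero_pseudocount, sums)
        rows.append(np.log(sums / total * scaling_factor))
    values = pd.DataFrame(np.vstack(rows), index=groups,
                          columns=counts.var_names.copy())
    return SubjectProfile(values, scaling_factor,
                          f"pseudocount {zero_pseudocount} on zero sums")
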