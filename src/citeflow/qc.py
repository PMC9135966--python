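"""Cell and feature quality control.

Per-cell statistics are computed from raw counts: total RNA UMIs, detected
genes, percent mitochondrial and ribosomal UMIs (by the MT-/RPS/RPL name
prefix convention), detected ADT features, and the percent of ADT counts
mapping to the isotype control antibodies.  Cells are retained when total
UMIs lie in [umi_min, umi_max] (inclusive), detected genes >= min_genes,
pct mito/ribo <= their caps, detected ADT features <= the cap, and percent
isotype strictly below its cap.  Cells without matched ADT data are exempt
from the ADT rules rather than auto-failing — such RNA-only cells are valid
input for the RNA analyses.

Feature QC removes genes with zero total count across retained cells and,
from the ADT panel, the isotype controls plus any caller-supplied exclusion
list (tags with expression inconsistent with annotated cell types).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad

from .config import QcThresholds

__all__ = ["QcReport", "compute_cell_qc", "filter_cells", "filter_features",
           "apply_qc"]

QC_FIELDS = ("n_umi", "n_genes", "pct_mito", "pct_ribo", "n_adt",
             "pct_isotype", "has_adt")


@dataclass
class QcReport:
    n_input: int = 0
    n_retained: int = 0
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    features_removed: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.n_input, "n_retained": self.n_retained,
            "removed_by_rule": self.removed_by_rule,
            "features_removed": {k: sorted(v) for k, v in self.features_removed.items()},
        }, indent=1)

    def log_lines(self) -> list[str]:
        lines = [f"cells: {self.n_retained}/{self.n_input} retained"]
        for rule, n in self.removed_by_rule.items():
            lines.append(f"  removed by {rule}: {n}")
        for kind, feats in self.features_removed.items():
            lines.append(f"features removed ({kind}): {len(feats)}")
        return lines


def compute_cell_qc(rna: ad.AnnData, adt: ad.AnnData | None = None) -> pd.DataFrame:
    """Per-cell QC statistics, returned as a DataFrame indexed by barcode.

    ``adt`` may cover a subset of the RNA cells (RNA-only libraries); cells
    without ADT rows get ``has_adt=False``.  Cells with an all-zero ADT row
    get 0 detected tags and pct_isotype defined as 0.
    """
    X = rna.X.tocsr()
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    is_mito = rna.var.get("is_mito", pd.Series(False, index=rna.var_names)).to_numpy()
    is_ribo = rna.var.get("is_ribo", pd.Series(False, index=rna.var_names)).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = 100.0 * np.asarray(X[:, is_mito].sum(axis=1)).ravel() / np.maximum(n_umi, 1)
        pct_ribo = 100.0 * np.asarray(X[:, is_ribo].sum(axis=1)).ravel() / np.maximum(n_umi, 1)
    qc = pd.DataFrame(
        {"n_umi": n_umi.astype(np.int64), "n_genes": n_genes.astype(np.int64),
         "pct_mito": pct_mito, "pct_ribo": pct_ribo},
        index=rna.obs_names.copy())
    qc["n_adt"] = 0
    qc["pct_isotype"] = 0.0
    qc["has_adt"] = False
    if adt is not None:
        common = rna.obs_names.intersection(adt.obs_names)
        if adt.n_obs and len(common) == 0:
            raise ValueError("RNA and ADT matrices share no cell barcodes")
        A = adt[common].X.tocsr()
        tot = np.asarray(A.sum(axis=1)).ravel()
        is_iso = adt.var.get("is_isotype",
                             pd.Series(False, index=adt.var_names)).to_numpy()
        iso = np.asarray(A[:, is_iso].sum(axis=1)).ravel()
        qc.loc[common, "n_adt"] = A.getnnz(axis=1)
        qc.loc[common, "pct_isotype"] = np.where(tot > 0, 100.0 * iso / np.maximum(tot, 1), 0.0)
        qc.loc[common, "has_adt"] = True
    return qc


def _failures(qc: pd.DataFrame, t: QcThresholds) -> dict[str, np.ndarray]:
    """Boolean failure mask per rule, in attribution order."""
    has_adt = qc["has_adt"].to_numpy(dtype=bool)
    return {
        "umi_min": (qc["n_umi"] < t.umi_min).to_numpy(),
        "umi_max": (qc["n_umi"] > t.umi_max).to_numpy(),
        "min_genes": (qc["n_genes"] < t.min_genes).to_numpy(),
        "max_pct_mito": (qc["pct_mito"] > t.max_pct_mito).to_numpy(),
        "max_pct_ribo": (qc["pct_ribo"] > t.max_pct_ribo).to_numpy(),
        "max_adt_features": has_adt & (qc["n_adt"] > t.max_adt_features).to_numpy(),
        "max_pct_isotype": has_adt & (qc["pct_isotype"] >= t.max_pct_isotype).to_numpy(),
    }


def filter_cells(qc: pd.DataFrame, t: QcThresholds) -> tuple[pd.Index, QcReport]:
    """Apply cell thresholds; returns retained barcodes and a report with
    first-failing-rule attribution (rule order = QcThresholds field order)."""
    missing = [f for f in QC_FIELDS if f not in qc.columns]
    if missing:
        raise ValueError(f"QC fields missing: {missing}")
    fails = _failures(qc, t)
    first = np.full(len(qc), "", dtype=object)
    for rule in QcThresholds.RULES:
        mask = fails[rule] & (first == "")
        first[mask] = rule
    retained = qc.index[first == ""]
    report = QcReport(
        n_input=len(qc), n_retained=len(retained),
        removed_by_rule={rule: int((first == rule).sum())
                         for rule in QcThresholds.RULES if (first == rule).any()},
    )
    report.first_fail = pd.Series(first, index=qc.index)  # type: ignore[attr-defined]
    return retained, report


def filter_features(rna: ad.AnnData, adt: ad.AnnData | None,
                    exclusion_list: list[str] | tuple[str, ...] = (),
                    report: QcReport | None = None,
                    ) -> tuple[ad.AnnData, ad.AnnData | None, QcReport]:
    """Remove zero-count genes and, from ADT, isotype controls and the
    exclusion-list tags.  Unknown exclusion names are an error."""
    report = report or QcReport(n_input=rna.n_obs, n_retained=rna.n_obs)
    totals = np.asarray(rna.X.sum(axis=0)).ravel()
    zero = rna.var_names[totals == 0]
    rna = rna[:, totals > 0].copy()
    report.features_removed["zero_count_genes"] = list(zero)
    if adt is not None:
        unknown = [x for x in exclusion_list if x not in adt.var_names]
        if unknown:
            raise ValueError(f"exclusion list names unknown ADT features: {unknown}")
        is_iso = adt.var.get("is_isotype",
                             pd.Series(False, index=adt.var_names)).to_numpy()
        drop = set(adt.var_names[is_iso]) | set(exclusion_list)
        keep = [f for f in adt.var_names if f not in drop]
        report.features_removed["isotype_tags"] = list(adt.var_names[is_iso])
        report.features_removed["excluded_tags"] = list(exclusion_list)
        adt = adt[:, keep].copy()
    return rna, adt, report


def apply_qc(rna: ad.AnnData, adt: ad.AnnData | None, t: QcThresholds,
             exclusion_list: tuple[str, ...] = (),
             ) -> tuple[ad.AnnData, ad.AnnData | None, QcReport]:
    """Full QC: compute stats, filter cells, then filter features.

    QC statistics are written into ``.obs`` of the returned objects.
    """
    qc = compute_cell_qc(rna, adt)
    retained, report = filter_cells(qc, t)
    rna = rna[retained].copy()
    for c in QC_FIELDS:
        rna.obs[c] = qc.loc[retained, c]
    if adt is not None:
        keep_adt = retained.intersection(adt.obs_names)
        adt = adt[keep_adt].copy()
    rna, adt, report = filter_features(rna, adt, exclusion_list, report)
    return rna, adt, report
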