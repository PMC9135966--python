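"""Per-subject cell-type composition and cohort comparison.

Each subject's cells are reduced to per-group fractions (of all retained
cells, or of the cells of a parent type for subcluster testing), and each
group is compared across cohorts with the two-sided Wilcoxon rank-sum
test: the exact null distribution when min(n1, n2) <= 10 and the data are
untied, a tie-corrected normal approximation otherwise.  Results are
reported unadjusted across groups — composition testing here is per-type,
not a corrected family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ProportionTable", "cell_type_proportions", "compare_proportions",
           "rank_sum_test"]


@dataclass
class ProportionTable:
    values: pd.DataFrame  # subjects × groups, fractions
    denominator: str  # "all cells" or "cells of <parent>"
    cohort_means: pd.DataFrame | None = None  # cohorts × groups
    cohort_sems: pd.DataFrame | None = None


def cell_type_proportions(meta: pd.DataFrame, group_col: str = "cell_type",
                          subject_col: str = "subject",
                          cohort_col: str = "cohort",
                          parent: str | None = None,
                          parent_col: str = "cell_type") -> ProportionTable:
    """Fraction of each subject's denominator cells in each group.

    With ``parent`` given, the denominator is each subject's cells of that
    parent type (used for within-type subcluster fractions); otherwise all
    of the subject's cells.  Subjects with an empty denominator get NaN
    rows, which downstream tests exclude.
    """
    df = meta
    if parent is not None:
        df = df[df[parent_col] == parent]
        denom_name = f"cells of {parent}"
    else:
        denom_name = "all cells"
    counts = (df.groupby([subject_col, group_col], observed=True).size()
                .unstack(fill_value=0))
    all_subjects = pd.Index(meta[subject_col].unique())
    counts = counts.reindex(all_subjects, fill_value=0)
    totals = counts.sum(axis=1)
    values = counts.div(totals.where(totals > 0), axis=0)

    cohort_of = (meta[[subject_col, cohort_col]].drop_duplicates()
                 .set_index(subject_col)[cohort_col])
    by_cohort = values.groupby(cohort_of.reindex(values.index), observed=True)
    means = by_cohort.mean()
    sems = by_cohort.sem(ddof=1)
    return ProportionTable(values, denom_name, means, sems)


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney).  Exact distribution when
    min(n) <= 10 and there are no ties; otherwise tie-corrected normal
    approximation.  Returns (U statistic for sample a, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("all values tied; rank-sum p set to 1")
        return float(len(a) * len(b) / 2.0), 1.0
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def compare_proportions(p: ProportionTable, cohorts: pd.Series,
                        group_a: str = "AS", group_b: str = "healthy"
                        ) -> pd.DataFrame:
    """Per-group cohort comparison of subject fractions.

    ``cohorts`` maps subject → cohort label.  Returns a DataFrame indexed by
    group with columns statistic, p, n_a, n_b, mean_a, mean_b.
    """
    cohorts = cohorts.reindex(p.values.index)
    rows = []
    for g in p.values.columns:
        col = p.values[g]
        a = col[(cohorts == group_a) & col.notna()].to_numpy()
        b = col[(cohorts == group_b) & col.notna()].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"group {g!r}: a cohort has no usable subjects")
        stat, pval = rank_sum_test(a, b)
        rows.append({"group": g, "statistic": stat, "p": pval,
                     "n_a": len(a), "n_b": len(b),
                     "mean_a": a.mean(), "mean_b": b.mean()})
    return pd.DataFrame(rows).set_index("group")
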