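"""Gene-set over-representation analysis against local GMT collections.

Differentially expressed gene lists are tested for enrichment in each term
of a user-supplied collection (GO/KEGG/Reactome/TF-target GMT files) with
the upper-tail hypergeometric probability of at least the observed overlap,
against a declared background (by default the genes tested for DE in the
same cell type).  Raw p-values are Benjamini–Hochberg adjusted within each
collection, mirroring a per-database FDR conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt",
           "enrich_hypergeometric"]


@dataclass
class GeneSetCollection:
    name: str
    sets: dict[str, set[str]]
    descriptions: dict[str, str] | None = None


def read_gmt(path: str | Path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per term — term, description,
    then member genes (duplicates within a line deduplicated)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line has "
                                 f"{len(fields)} fields, need >= 3")
            term, description, *genes = fields
            sets[term] = {g for g in genes if g}
            desc[term] = description
    if not sets:
        warnings.warn(f"{path}: empty GMT collection")
    return GeneSetCollection(name or path.stem, sets, desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in collection.sets.items():
            d = (collection.descriptions or {}).get(term, "")
            fh.write("\t".join([term, d] + sorted(genes)) + "\n")


def enrich_hypergeometric(query: set[str] | list[str],
                          collection: GeneSetCollection,
                          background: set[str] | list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Sets are intersected with the background before testing; the query must
    be a subset of the background.  Returns results sorted by p, with BH
    FDR within the collection.
    """
    query = set(query)
    background = set(background)
    if not query:
        return pd.DataFrame(columns=["term", "collection", "overlap",
                                     "query_size", "set_size",
                                     "background_size", "p", "fdr"])
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    N = len(background)
    n = len(query)
    rows = []
    for term, genes in collection.sets.items():
        s = genes & background
        K = len(s)
        if K == 0:
            continue
        k = len(s & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "collection": collection.name,
                     "overlap": k, "query_size": n, "set_size": K,
                     "background_size": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
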