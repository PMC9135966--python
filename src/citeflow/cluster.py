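"""Intra-cell-type clustering: variable features, batch standardization,
PCA, shared-nearest-neighbor graph, Louvain communities, and cluster
overrepresentation testing across cohorts.

The cross-batch integration step is a per-batch standardization (each
feature centered and unit-scaled within its batch), whose testable contract
is that batch is not separable in the resulting embedding on simulated
batch effects.  The SNN graph weights edges by the Jaccard overlap of
k-nearest-neighbor lists (self excluded) and prunes weights <= 1/15 by
default; communities maximize resolution-parameterized modularity via the
Louvain method with a seeded generator, and labels are relabeled by
decreasing cluster size so fixed seeds give identical labelings.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd

from .composition import ProportionTable, compare_proportions
from .normalize import NormalizedMatrix

__all__ = ["ClusterResult", "select_variable_features", "batch_standardize",
           "pca_embed", "snn_graph", "louvain_cluster",
           "cluster_overrepresentation"]


@dataclass
class ClusterResult:
    labels: pd.Series  # cell -> cluster id (consecutive ints from 0)
    embedding: np.ndarray  # cells × n_pcs
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def select_variable_features(m: NormalizedMatrix, batches: pd.Series | None = None,
                             n: int = 3000) -> pd.Index:
    """Top-n features by residual variance, aggregated as the median of
    within-batch variance ranks (rank 0 = most variable)."""
    if n >= len(m.features):
        if n > len(m.features):
            warnings.warn(f"requested {n} features but only "
                          f"{len(m.features)} available; returning all")
        return m.features.copy()
    if batches is None:
        bvec = np.zeros(len(m.cells), dtype=int)
    else:
        bvec = np.asarray(pd.Series(batches).reindex(m.cells))
    ranks = []
    for b in pd.unique(bvec):
        v = m.values[bvec == b].var(axis=0, ddof=1) if (bvec == b).sum() > 1 \
            else np.zeros(len(m.features))
        order = pd.Series(-v, index=m.features).rank(method="average")
        ranks.append(order)
    med = pd.concat(ranks, axis=1).median(axis=1)
    top = med.sort_values(kind="stable").index[:n]
    return pd.Index([f for f in m.features if f in set(top)])  # keep input order


def batch_standardize(m: NormalizedMatrix, batches: pd.Series) -> NormalizedMatrix:
    """Center and unit-scale each feature within each batch (n−1 denominator);
    zero-variance-in-batch features map to 0.  Single-cell batches are only
    centered."""
    bvec = np.asarray(pd.Series(batches).reindex(m.cells))
    out = np.empty_like(m.values, dtype=np.float64)
    for b in pd.unique(bvec):
        mask = bvec == b
        block = m.values[mask]
        mu = block.mean(axis=0, keepdims=True)
        if mask.sum() > 1:
            sd = block.std(axis=0, ddof=1)
            out[mask] = np.where(sd > 0, (block - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        else:
            warnings.warn(f"batch {b!r} has a single cell; centered only")
            out[mask] = block - mu
    return NormalizedMatrix(out, m.cells, m.features, m.method,
                            {**m.params, "batch_standardized": True})


def pca_embed(m: NormalizedMatrix, n_pcs: int = 30) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA scores of the centered matrix.

    Returns (scores cells × n_pcs, loadings features × n_pcs, explained
    variances).  Component signs are fixed so each loading vector's
    largest-magnitude entry is positive.
    """
    max_pcs = min(len(m.cells), len(m.features))
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} clamped to {max_pcs}")
        n_pcs = max_pcs
    Xc = m.values - m.values.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :n_pcs], s[:n_pcs], Vt[:n_pcs]
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    expl_var = s ** 2 / max(len(m.cells) - 1, 1)
    return scores, Vt.T, expl_var


def snn_graph(embedding: np.ndarray, k: int = 20,
              prune: float = 1.0 / 15.0) -> igraph.Graph:
    """Shared-nearest-neighbor graph on a PCA embedding.

    Euclidean k-nearest neighbors per cell (self excluded, distance ties
    broken by cell index); edges between cells that are neighbors of each
    other's lists, weighted by Jaccard overlap of the lists; weights <=
    ``prune`` removed.
    """
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    neigh = []
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        neigh.append(set(row))
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in neigh[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            w = inter / union if union else 0.0
            if w > prune:
                edges.append((a, b))
                weights.append(w)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def louvain_cluster(graph: igraph.Graph, resolution: float = 0.6,
                    seed: int = 0, embedding: np.ndarray | None = None
                    ) -> ClusterResult:
    """Louvain community detection at the given resolution, deterministic
    for a fixed seed; labels sorted by decreasing cluster size (ties by
    smallest member index)."""
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    if graph.ecount() == 0:
        warnings.warn("graph has no edges; every cell is its own cluster")
        membership = list(range(graph.vcount()))
    else:
        state = random.Random(seed)
        igraph.set_random_number_generator(state)
        try:
            part = graph.community_multilevel(weights="weight",
                                              resolution=resolution)
        finally:
            igraph.set_random_number_generator(random)
        membership = part.membership
    labels = _relabel_by_size(np.asarray(membership))
    return ClusterResult(
        labels=pd.Series(labels),
        embedding=embedding if embedding is not None else np.empty((graph.vcount(), 0)),
        params={"resolution": resolution, "seed": seed})


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    first = {c: int(np.flatnonzero(labels == c)[0]) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels])


def cluster_overrepresentation(result: ClusterResult, meta: pd.DataFrame,
                               *, subject_col: str = "subject",
                               cohort_col: str = "cohort",
                               group_a: str = "AS",
                               group_b: str = "healthy") -> pd.DataFrame:
    """Test each cluster for cohort overrepresentation.

    Each subject's fraction of its (parent-type) cells belonging to the
    cluster is compared across cohorts with the rank-sum test.  ``meta``
    holds the rows for the clustered cells only, in the same order as
    ``result.labels``.
    """
    df = meta.copy()
    df["cluster"] = [f"cluster{c}" for c in result.labels.to_numpy()]
    counts = (df.groupby([subject_col, "cluster"], observed=True).size()
              .unstack(fill_value=0))
    totals = counts.sum(axis=1)
    values = counts.div(totals.where(totals > 0), axis=0)
    table = ProportionTable(values, "cells of parent type")
    cohorts = (df[[subject_col, cohort_col]].drop_duplicates()
               .set_index(subject_col)[cohort_col])
    return compare_proportions(table, cohorts, group_a, group_b)
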