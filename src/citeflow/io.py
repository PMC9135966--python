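"""Reading and writing the 10x-style on-disk layout.

Each modality is a triplet directory: ``matrix.mtx`` (MatrixMarket
coordinate format, features × cells, 1-based indices), ``features.tsv``
(id, name, modality, flags) and ``barcodes.tsv``.  Cell and subject
metadata are tab-separated tables with headers; planted truth is JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io
import anndata as ad

from .simdata import SimDataset, SimTruth

__all__ = ["write_10x", "read_10x", "read_dataset", "MtxParseError"]

_FLAG_COLS = {"mito": "is_mito", "ribo": "is_ribo", "isotype": "is_isotype"}


class MtxParseError(ValueError):
    pass


def write_10x(adata: ad.AnnData, outdir: str | Path, modality: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csc_matrix(adata.X).T.tocoo()  # features x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X, field="integer")
    flags = []
    for _, row in adata.var.iterrows():
        f = [short for short, col in _FLAG_COLS.items() if row.get(col, False)]
        flags.append(";".join(f))
    feats = pd.DataFrame({
        "id": adata.var_names, "name": adata.var_names,
        "modality": modality, "flags": flags})
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv",
                                      sep="\t", index=False, header=False)


def _read_mtx(path: Path) -> sp.coo_matrix:
    """Coordinate MatrixMarket reader with explicit header/entry validation."""
    with open(path) as fh:
        header = fh.readline()
        if "matrixmarket" not in header.lower() or "coordinate" not in header.lower():
            raise MtxParseError(f"{path}: not a coordinate MatrixMarket file")
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        try:
            n_rows, n_cols, n_entries = (int(x) for x in line.split())
        except ValueError as e:
            raise MtxParseError(f"{path}: bad size line {line!r}") from e
        data = np.loadtxt(fh, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 3))
    if data.shape[0] != n_entries:
        raise MtxParseError(
            f"{path}: header declares {n_entries} entries but "
            f"{data.shape[0]} of {n_entries} present")
    i = data[:, 0].astype(np.int64)
    j = data[:, 1].astype(np.int64)
    if len(i) and (i.min() < 1 or j.min() < 1 or i.max() > n_rows or j.max() > n_cols):
        raise MtxParseError(f"{path}: 1-based indices out of declared bounds")
    return sp.coo_matrix((data[:, 2], (i - 1, j - 1)), shape=(n_rows, n_cols))


def read_10x(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    X = _read_mtx(indir / "matrix.mtx")
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None,
                        names=["id", "name", "modality", "flags"], dtype=str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    if X.shape[0] != len(feats) or X.shape[1] != len(barcodes):
        raise MtxParseError(
            f"{indir}: matrix is {X.shape} but features/barcodes are "
            f"{len(feats)}/{len(barcodes)}")
    var = pd.DataFrame(index=pd.Index(feats["id"], name="feature"))
    flags = feats["flags"].fillna("")
    for short, col in _FLAG_COLS.items():
        vals = flags.str.split(";").apply(lambda f: short in f).to_numpy()
        if vals.any():
            var[col] = vals
    var["modality"] = feats["modality"].to_numpy()
    return ad.AnnData(X=sp.csr_matrix(X.T.astype(np.int32)),
                      obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
                      var=var)


def read_dataset(indir: str | Path) -> SimDataset:
    """Read a dataset directory back into memory.

    Matrices are realigned to the cell_meta row order by barcode id, so a
    permuted barcodes.tsv on disk round-trips to the same in-memory object.
    """
    indir = Path(indir)
    meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t", index_col=0)
    rna = read_10x(indir / "rna")
    adt = read_10x(indir / "adt") if (indir / "adt" / "matrix.mtx").exists() else None

    def _align(adata: ad.AnnData) -> ad.AnnData:
        missing = meta.index.difference(adata.obs_names)
        if len(missing):
            raise ValueError(f"cell_meta barcodes absent from matrix: "
                             f"{list(missing[:5])}")
        adata = adata[meta.index].copy()
        for c in meta.columns:
            adata.obs[c] = meta[c].values
        return adata

    rna = _align(rna)
    truth_path = indir / "truth.json"
    truth = (SimTruth.from_json(truth_path.read_text()) if truth_path.exists()
             else SimTruth([], {}, [], {}))
    if adt is not None:
        adt = _align(adt)
    return SimDataset(rna=rna, adt=adt, subject_meta=subjects, truth=truth)
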