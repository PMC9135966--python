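"""Synthetic CITE-seq cohort generator.

Generates a two-cohort (AS vs healthy) multimodal single-cell dataset with
the statistical structure the downstream analysis assumes: negative-binomial
RNA counts (Gamma–Poisson mixture) with per-gene dispersion, cell-type
expression profiles, multiplicative per-batch factors (including one large
"artifact" gene per batch to exercise the batch-artifact filter), ADT counts
with a uniform nonspecific background and background-only isotype controls,
per-subject cell-type mixtures drawn from a Dirichlet whose concentration
encodes cohort composition shifts, an optional planted subcluster inside a
parent cell type, and cells planted to violate specific QC rules.  All
planted structure is recorded in a :class:`SimTruth` for recovery tests.

The default configuration mirrors the study cohort shape — 29 healthy and
10 AS subjects across 3 sequencing batches, ADT panel with 9 isotype
controls, mitochondrial/ribosomal genes flagged by name prefix — at desk
scale (hundreds of cells per subject, hundreds of genes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

__all__ = [
    "CellTypeSpec",
    "PlantedEffect",
    "SubclusterSpec",
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "generate_cohort",
    "doublet_mixin",
    "write_dataset",
    "null_config",
    "strong_effect_config",
]

_ADT_MARKER_NAMES = [
    "CD3", "CD4", "CD8", "CD14", "CD16", "CD56", "CD19", "CD25", "CD38",
    "CD45RA", "CD45RO", "CD127", "CD161", "PD-1", "CCR6", "CD5", "CD74",
    "CD52", "HLA-DR", "CD27", "CD28", "CD57", "CD69", "CD86", "CD11c",
]


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    weight: float  # baseline mixture weight (healthy cohort)
    profile_scale: float = 0.8  # sd of per-gene log-normal type factor


@dataclass(frozen=True)
class PlantedEffect:
    cell_type: str
    feature: str
    modality: str  # "RNA" | "ADT"
    log2fc: float  # applied to AS cells of cell_type


@dataclass(frozen=True)
class SubclusterSpec:
    parent: str
    rna_markers: tuple[str, ...]
    adt_markers: tuple[str, ...]
    marker_log2fc: float = 2.0
    base_rate: float = 0.10  # membership probability, healthy cells of parent
    as_enrichment: float = 3.0  # multiplies base_rate for AS cells


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the study cohort at desk scale."""

    n_healthy: int = 29
    n_as: int = 10
    cells_per_subject: int = 200
    n_genes: int = 500
    n_mito: int = 10
    n_ribo: int = 40
    n_adt: int = 30  # includes the 9 isotype controls
    n_isotype: int = 9
    n_batches: int = 3
    cell_types: tuple[CellTypeSpec, ...] = (
        CellTypeSpec("CD4 T", 0.30),
        CellTypeSpec("CD8 T", 0.20),
        CellTypeSpec("NK", 0.12),
        CellTypeSpec("B", 0.12),
        CellTypeSpec("CD14 Mono", 0.20),
        CellTypeSpec("DC", 0.06),
    )
    de_spec: tuple[PlantedEffect, ...] = ()
    composition_spec: dict[str, float] = field(default_factory=dict)
    subcluster_spec: SubclusterSpec | None = None
    qc_outlier_rate: float = 0.0  # per planted QC rule
    dispersion_range: tuple[float, float] = (5.0, 50.0)  # NB size theta
    libsize_lognormal: tuple[float, float] = (np.log(2500.0), 0.30)
    adt_libsize_lognormal: tuple[float, float] = (np.log(1200.0), 0.30)
    mito_fraction: float = 0.06
    ribo_fraction: float = 0.30
    batch_sigma: float = 0.15
    artifact_fold: float = 10.0  # per-batch artifact gene factor; 1 disables
    adt_background_max: int = 2  # uniform background counts per tag, 0..max
    dirichlet_concentration: float = 150.0
    confound_batch_cohort: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_healthy, self.n_as, self.cells_per_subject,
               self.n_genes, self.n_adt, self.n_batches) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_adt < 10 or self.n_isotype != 9:
            raise ValueError("ADT panel needs >= 10 tags including 9 isotype controls")
        if not 0 <= self.qc_outlier_rate < 1:
            raise ValueError("qc_outlier_rate must be in [0, 1)")
        if self.n_mito + self.n_ribo >= self.n_genes:
            raise ValueError("n_mito + n_ribo must be < n_genes")
        w = sum(ct.weight for ct in self.cell_types)
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"cell type weights must sum to 1, got {w}")
        names = {ct.name for ct in self.cell_types}
        for t in self.composition_spec:
            if t not in names:
                raise ValueError(f"composition_spec names unknown cell type {t!r}")
        if self.subcluster_spec and self.subcluster_spec.parent not in names:
            raise ValueError(
                f"subcluster parent {self.subcluster_spec.parent!r} is not a cell type")


@dataclass
class SimTruth:
    """Planted ground truth of a generated dataset."""

    planted_de: list[dict]
    planted_composition: dict[str, float]
    planted_subcluster: list[str]  # barcodes
    outlier_cells: dict[str, str]  # barcode -> violated rule
    doublets: list[str] = field(default_factory=list)
    batch_artifact_genes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


@dataclass
class SimDataset:
    rna: ad.AnnData
    adt: ad.AnnData
    subject_meta: pd.DataFrame  # index subject, column "cohort"
    truth: SimTruth

    @property
    def cell_meta(self) -> pd.DataFrame:
        return self.rna.obs


# --------------------------------------------------------------------------
# deterministic model construction (noiseless mean parameters)
# --------------------------------------------------------------------------

def _feature_names(cfg: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    names, is_mito, is_ribo = [], [], []
    for i in range(cfg.n_mito):
        names.append(f"MT-G{i + 1}")
    for i in range(cfg.n_ribo):
        names.append((f"RPS{i + 1}" if i % 2 == 0 else f"RPL{i + 1}"))
    for i in range(cfg.n_genes - cfg.n_mito - cfg.n_ribo):
        names.append(f"GENE{i + 1:04d}")
    is_mito = np.array([n.startswith("MT-") for n in names])
    is_ribo = np.array([n.startswith(("RPS", "RPL")) for n in names])
    return names, is_mito, is_ribo


def _adt_names(cfg: SimConfig) -> tuple[list[str], np.ndarray]:
    n_marker = cfg.n_adt - cfg.n_isotype
    names = [_ADT_MARKER_NAMES[i] if i < len(_ADT_MARKER_NAMES) else f"ADT{i + 1}"
             for i in range(n_marker)]
    names += [f"IsoCtrl{i + 1}" for i in range(cfg.n_isotype)]
    is_isotype = np.array([n.startswith("IsoCtrl") for n in names])
    return names, is_isotype


def build_model(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Draw the deterministic mean model: per-type gene/tag profiles, batch
    factors, dispersions, cohort mixtures.  All noiseless parameters."""
    gene_names, is_mito, is_ribo = _feature_names(cfg)
    adt_names, is_isotype = _adt_names(cfg)
    type_names = [ct.name for ct in cfg.cell_types]

    base = rng.lognormal(0.0, 1.0, cfg.n_genes)
    profiles = {}
    for ct in cfg.cell_types:
        f = rng.lognormal(0.0, ct.profile_scale, cfg.n_genes)
        p = base * f
        # fix mito/ribo mass so QC percentages sit in a realistic range
        other = ~(is_mito | is_ribo)
        p[is_mito] *= cfg.mito_fraction / p[is_mito].sum()
        p[is_ribo] *= cfg.ribo_fraction / p[is_ribo].sum()
        p[other] *= (1.0 - cfg.mito_fraction - cfg.ribo_fraction) / p[other].sum()
        profiles[ct.name] = p

    # ADT marker profiles: markers only; isotype controls carry no signal
    adt_profiles = {}
    n_marker = cfg.n_adt - cfg.n_isotype
    for ct in cfg.cell_types:
        q = rng.lognormal(0.0, 1.0, cfg.n_adt)
        q[is_isotype] = 0.0
        q[:n_marker] /= q[:n_marker].sum()
        adt_profiles[ct.name] = q

    batch_names = [f"batch{k + 1}" for k in range(cfg.n_batches)]
    batch_factors = {}
    artifact_genes = {}
    eligible = [g for g, m, r in zip(gene_names, is_mito, is_ribo) if not (m or r)]
    for k, b in enumerate(batch_names):
        bf = rng.lognormal(0.0, cfg.batch_sigma, cfg.n_genes)
        if cfg.artifact_fold != 1.0 and cfg.n_batches > 1:
            g = eligible[(7 * k) % len(eligible)]
            bf[gene_names.index(g)] *= cfg.artifact_fold
            artifact_genes[b] = g
        batch_factors[b] = bf

    lo, hi = cfg.dispersion_range
    theta = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes))
    theta_adt = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_adt))

    # cohort mixture weights
    w = np.array([ct.weight for ct in cfg.cell_types])
    logit = np.log(w)
    shift = np.array([cfg.composition_spec.get(t, 0.0) for t in type_names])
    w_as = np.exp(logit + shift)
    w_as /= w_as.sum()
    return {
        "gene_names": gene_names, "is_mito": is_mito, "is_ribo": is_ribo,
        "adt_names": adt_names, "is_isotype": is_isotype,
        "type_names": type_names, "profiles": profiles,
        "adt_profiles": adt_profiles, "batch_names": batch_names,
        "batch_factors": batch_factors, "artifact_genes": artifact_genes,
        "theta": theta, "theta_adt": theta_adt,
        "weights_healthy": w, "weights_as": w_as,
    }


def _validate_de_spec(cfg: SimConfig, model: dict) -> None:
    genes = set(model["gene_names"])
    tags = set(model["adt_names"])
    types = set(model["type_names"])
    for e in cfg.de_spec:
        if e.cell_type not in types:
            raise ValueError(f"planted effect on unknown cell type: {e}")
        pool = genes if e.modality == "RNA" else tags
        if e.modality not in ("RNA", "ADT"):
            raise ValueError(f"planted effect with unknown modality: {e}")
        if e.feature not in pool:
            raise ValueError(f"planted effect on nonexistent feature: {e}")
    if cfg.subcluster_spec:
        sc = cfg.subcluster_spec
        missing = [m for m in sc.rna_markers if m not in genes]
        missing += [m for m in sc.adt_markers if m not in tags]
        if missing:
            raise ValueError(f"subcluster markers not in panel: {missing}")


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

_QC_PLANT_RULES = ("umi_min", "umi_max", "max_pct_mito", "max_pct_ribo",
                   "max_pct_isotype")


def generate_cohort(cfg: SimConfig) -> SimDataset:
    """Generate a full synthetic cohort.  Identical config (including seed)
    yields a byte-identical dataset."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    model = build_model(cfg, rng)
    _validate_de_spec(cfg, model)

    subjects = [f"H{i + 1:02d}" for i in range(cfg.n_healthy)] + \
               [f"AS{i + 1:02d}" for i in range(cfg.n_as)]
    cohorts = ["healthy"] * cfg.n_healthy + ["AS"] * cfg.n_as
    if cfg.confound_batch_cohort:
        batch_of = {s: model["batch_names"][min(int(i * cfg.n_batches / len(subjects)),
                                                cfg.n_batches - 1)]
                    for i, s in enumerate(subjects)}
    else:
        batch_of = {s: model["batch_names"][i % cfg.n_batches]
                    for i, s in enumerate(subjects)}

    n_cells = len(subjects) * cfg.cells_per_subject
    barcodes = [f"CELL{i + 1:06d}" for i in range(n_cells)]

    # per-subject mixtures and cell type assignment
    conc = cfg.dirichlet_concentration
    cell_subject = np.repeat(subjects, cfg.cells_per_subject)
    cell_cohort = np.repeat(cohorts, cfg.cells_per_subject)
    cell_type = np.empty(n_cells, dtype=object)
    tn = model["type_names"]
    for i, (s, coh) in enumerate(zip(subjects, cohorts)):
        w = model["weights_healthy"] if coh == "healthy" else model["weights_as"]
        mix = rng.dirichlet(conc * w)
        idx = rng.choice(len(tn), size=cfg.cells_per_subject, p=mix)
        cell_type[i * cfg.cells_per_subject:(i + 1) * cfg.cells_per_subject] = \
            [tn[j] for j in idx]
    cell_batch = np.array([batch_of[s] for s in cell_subject], dtype=object)

    # subcluster membership
    in_sub = np.zeros(n_cells, dtype=bool)
    sc = cfg.subcluster_spec
    if sc is not None:
        parent = cell_type == sc.parent
        p_mem = np.where(cell_cohort == "AS",
                         min(sc.base_rate * sc.as_enrichment, 0.9), sc.base_rate)
        in_sub = parent & (rng.random(n_cells) < p_mem)

    # planted QC outliers (disjoint across rules)
    outlier_rule = np.full(n_cells, "", dtype=object)
    if cfg.qc_outlier_rate > 0:
        n_per_rule = max(1, round(cfg.qc_outlier_rate * n_cells))
        pool = rng.permutation(n_cells)
        k = 0
        for rule in _QC_PLANT_RULES:
            take = pool[k:k + n_per_rule]
            outlier_rule[take] = rule
            k += n_per_rule

    # library sizes
    mlog, sdlog = cfg.libsize_lognormal
    libsize = rng.lognormal(mlog, sdlog, n_cells)
    libsize = np.clip(libsize, 600, 9000)  # keep regular cells inside QC bounds
    libsize[outlier_rule == "umi_min"] = 250.0
    libsize[outlier_rule == "umi_max"] = 14000.0
    # percentage-rule outliers get a mid-range library size so they violate
    # only their planted rule (not the detected-genes floor)
    pct_rules = np.isin(outlier_rule, ("max_pct_mito", "max_pct_ribo"))
    libsize[pct_rules] = float(np.clip(np.exp(mlog), 1500, 9000))
    amlog, asdlog = cfg.adt_libsize_lognormal
    adt_lib = rng.lognormal(amlog, asdlog, n_cells)

    gene_idx = {g: j for j, g in enumerate(model["gene_names"])}
    tag_idx = {t: j for j, t in enumerate(model["adt_names"])}
    rna_fx = {}  # (type) -> extra log2 factors per gene for AS cells
    adt_fx = {}
    for e in cfg.de_spec:
        d = rna_fx if e.modality == "RNA" else adt_fx
        v = d.setdefault(e.cell_type,
                         np.zeros(cfg.n_genes if e.modality == "RNA" else cfg.n_adt))
        v[(gene_idx if e.modality == "RNA" else tag_idx)[e.feature]] += e.log2fc

    is_mito, is_ribo = model["is_mito"], model["is_ribo"]
    is_iso = model["is_isotype"]
    n_marker = cfg.n_adt - cfg.n_isotype

    rna_rows = np.empty((n_cells, cfg.n_genes), dtype=np.int32)
    adt_rows = np.empty((n_cells, cfg.n_adt), dtype=np.int32)
    theta, theta_adt = model["theta"], model["theta_adt"]

    for i in range(n_cells):
        t, coh, b = cell_type[i], cell_cohort[i], cell_batch[i]
        p = model["profiles"][t] * model["batch_factors"][b]
        if coh == "AS" and t in rna_fx:
            p = p * np.exp2(rna_fx[t])
        if sc is not None and in_sub[i]:
            mk = np.zeros(cfg.n_genes)
            for m in sc.rna_markers:
                mk[gene_idx[m]] = sc.marker_log2fc
            p = p * np.exp2(mk)
        rule = outlier_rule[i]
        if rule in ("max_pct_mito", "max_pct_ribo"):
            # rescale the class block so its final share (after per-cell
            # renormalization) hits the target fraction q
            mask = is_mito if rule == "max_pct_mito" else is_ribo
            q = 0.35 if rule == "max_pct_mito" else 0.75
            p = p.copy()
            s = p[mask].sum() / p.sum()
            p[mask] *= q * (1 - s) / (s * (1 - q))
        mu = libsize[i] * p / p.sum()
        lam = rng.gamma(theta, mu / theta)
        rna_rows[i] = rng.poisson(lam)

        q = model["adt_profiles"][t].copy()
        if coh == "AS" and t in adt_fx:
            q[:n_marker] *= np.exp2(adt_fx[t][:n_marker])
        if sc is not None and in_sub[i]:
            for m in sc.adt_markers:
                q[tag_idx[m]] *= 2.0 ** sc.marker_log2fc
        qsum = q.sum()
        mu_a = adt_lib[i] * q / qsum if qsum > 0 else np.zeros(cfg.n_adt)
        lam_a = np.where(mu_a > 0, rng.gamma(theta_adt, np.maximum(mu_a, 1e-12) / theta_adt), 0.0)
        counts_a = rng.poisson(lam_a)
        counts_a += rng.integers(0, cfg.adt_background_max + 1, cfg.n_adt)
        if rule == "max_pct_isotype":
            # boost isotype share to ~8% of the cell's ADT counts
            total = counts_a.sum()
            boost = max(int(0.08 * total), 1)
            counts_a[is_iso] += rng.multinomial(boost, np.ones(is_iso.sum()) / is_iso.sum())
        adt_rows[i] = counts_a

    obs = pd.DataFrame(
        {"subject": pd.Categorical(cell_subject),
         "batch": pd.Categorical(cell_batch),
         "cohort": pd.Categorical(cell_cohort),
         "cell_type": pd.Categorical(cell_type.astype(str))},
        index=pd.Index(barcodes, name="barcode"))
    rna_var = pd.DataFrame(
        {"is_mito": is_mito, "is_ribo": is_ribo},
        index=pd.Index(model["gene_names"], name="feature"))
    adt_var = pd.DataFrame(
        {"is_isotype": is_iso},
        index=pd.Index(model["adt_names"], name="feature"))
    rna = ad.AnnData(X=sp.csr_matrix(rna_rows), obs=obs, var=rna_var)
    adt = ad.AnnData(X=sp.csr_matrix(adt_rows), obs=obs.copy(), var=adt_var)

    subject_meta = pd.DataFrame({"cohort": cohorts},
                                index=pd.Index(subjects, name="subject"))
    truth = SimTruth(
        planted_de=[asdict(e) for e in cfg.de_spec],
        planted_composition=dict(cfg.composition_spec),
        planted_subcluster=[barcodes[i] for i in np.flatnonzero(in_sub)],
        outlier_cells={barcodes[i]: outlier_rule[i]
                       for i in np.flatnonzero(outlier_rule != "")},
        batch_artifact_genes=dict(model["artifact_genes"]),
    )
    return SimDataset(rna=rna, adt=adt, subject_meta=subject_meta, truth=truth)


def doublet_mixin(dataset: SimDataset, rate: float, seed: int) -> SimDataset:
    """Append planted doublets: feature-wise sums of two random cells.

    Doublets inherit the first parent's metadata and are listed in
    ``truth.doublets``.  ``rate`` is the fraction of the original cell count
    added as doublets, in [0, 0.5).
    """
    if not 0 <= rate < 0.5:
        raise ValueError(f"doublet rate must be in [0, 0.5), got {rate}")
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    n = dataset.rna.n_obs
    n_doub = int(round(rate * n))
    pairs = np.stack([rng.choice(n, n_doub, replace=True),
                      rng.choice(n, n_doub, replace=True)], axis=1)
    names = [f"DBL{i + 1:06d}" for i in range(n_doub)]

    def _extend(adata: ad.AnnData) -> ad.AnnData:
        X = adata.X.tocsr()
        extra = X[pairs[:, 0]] + X[pairs[:, 1]]
        obs = adata.obs.iloc[pairs[:, 0]].copy()
        obs.index = pd.Index(names, name="barcode")
        new = ad.AnnData(X=sp.vstack([X, extra]).tocsr(),
                         obs=pd.concat([adata.obs, obs]), var=adata.var.copy())
        return new

    truth = SimTruth(**{**asdict(dataset.truth), "doublets": list(names)})
    return SimDataset(rna=_extend(dataset.rna), adt=_extend(dataset.adt),
                      subject_meta=dataset.subject_meta.copy(), truth=truth)


# --------------------------------------------------------------------------
# study-condition presets
# --------------------------------------------------------------------------

def null_config(seed: int = 0, *, n_genes: int = 500,
                cells_per_group: int = 200) -> SimConfig:
    """Global-null cohort for error-rate calibration: one cell type, one
    batch, no planted effects; two groups of ``cells_per_group`` cells."""
    per_subj = cells_per_group // 2
    return SimConfig(
        n_healthy=2, n_as=2, cells_per_subject=per_subj, n_genes=n_genes,
        n_mito=6, n_ribo=24, n_batches=1, artifact_fold=1.0,
        cell_types=(CellTypeSpec("T", 1.0, 0.0),),
        seed=seed)


def strong_effect_config(seed: int = 0, *, cells_per_subject: int = 200) -> SimConfig:
    """Cohort with strong planted cell-type-specific disease effects in both
    modalities: 12 RNA and 6 ADT features at |log2 effect| >= 1 across four
    cell types — the synthetic analog of strong disease biology."""
    rna_feats = [f"GENE{i:04d}" for i in range(1, 13)]
    effects = []
    types = ["CD4 T", "CD8 T", "NK", "CD14 Mono"]
    lfcs = [1.0, -1.0, 1.5, -1.5, 1.2, 1.0, -1.2, 1.5, 1.0, -1.0, 1.2, -1.5]
    for i, (g, lfc) in enumerate(zip(rna_feats, lfcs)):
        effects.append(PlantedEffect(types[i % 4], g, "RNA", lfc))
    adt_feats = ["CD16", "CD38", "CD127", "CD25", "CD5", "CCR6"]
    adt_lfcs = [1.5, 1.0, -1.0, 1.2, -1.2, 1.0]
    adt_types = ["NK", "NK", "CD4 T", "CD4 T", "B", "B"]
    for t, f, lfc in zip(adt_types, adt_feats, adt_lfcs):
        effects.append(PlantedEffect(t, f, "ADT", lfc))
    return SimConfig(de_spec=tuple(effects), cells_per_subject=cells_per_subject,
                     seed=seed)


# --------------------------------------------------------------------------
# on-disk 10x-style layout
# --------------------------------------------------------------------------

def write_dataset(ds: SimDataset, outdir: str | Path) -> None:
    """Write 10x-style triplets per modality plus metadata tables and truth.

    Layout: ``rna/`` and ``adt/`` each with matrix.mtx (features × cells,
    1-based coordinate MatrixMarket), features.tsv, barcodes.tsv; top level
    cell_meta.tsv, subjects.tsv, truth.json.
    """
    from . import io as cio

    outdir = Path(outdir)
    cio.write_10x(ds.rna, outdir / "rna", modality="RNA")
    cio.write_10x(ds.adt, outdir / "adt", modality="ADT")
    ds.rna.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")
    ds.subject_meta.to_csv(outdir / "subjects.tsv", sep="\t")
    (outdir / "truth.json").write_text(ds.truth.to_json())
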