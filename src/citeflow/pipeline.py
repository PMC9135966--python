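"""End-to-end pipeline over a work directory.

Each stage reads its inputs from, and writes its outputs to, a work
directory, so the CLI subcommands and :func:`run_pipeline` (which simply
chains the same stage functions) produce identical outputs by
construction.  Stage order: simulate-or-read → QC → normalize →
composition → per-cell-type DE (+ batch-artifact filter) → clustering and
overrepresentation (for configured target types) → enrichment (if
collections are given) → subject feature matrix → ensemble selection →
training → held-out evaluation.

A run manifest records the config hash, the master seed and every derived
stage seed, and per-stage input/output shapes; identical config and seed
reproduce an identical manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from . import diffexpr, mlpipe, normalize, qc
from .config import PipelineConfig, stage_seed
from .io import read_dataset
from .simdata import SimConfig, SimDataset, generate_cohort, write_dataset

log = logging.getLogger("citeflow")

__all__ = ["RunManifest", "run_pipeline", "stage_simulate", "stage_qc",
           "stage_normalize", "stage_composition", "stage_de",
           "stage_cluster", "stage_enrich", "stage_ml"]

STAGES = ("simulate", "qc", "normalize", "composition", "de", "cluster",
          "enrich", "ml")


@dataclass
class RunManifest:
    config_hash: str = ""
    seed: int = 0
    stage_seeds: dict[str, int] = field(default_factory=dict)
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, **shapes) -> None:
        self.stages.append({"stage": name, **shapes})
        log.info("stage %s: %s", name, shapes)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, default=str))


def _float_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(simcfg: SimConfig, workdir: Path,
                   manifest: RunManifest | None = None) -> None:
    ds = generate_cohort(simcfg)
    write_dataset(ds, Path(workdir) / "dataset")
    if manifest:
        manifest.record("simulate", cells=ds.rna.n_obs, genes=ds.rna.n_vars,
                        adt=ds.adt.n_vars, subjects=len(ds.subject_meta))


def stage_qc(workdir: Path, cfg: PipelineConfig,
             manifest: RunManifest | None = None) -> None:
    workdir = Path(workdir)
    ds = read_dataset(workdir / "dataset")
    rna, adt, report = qc.apply_qc(ds.rna, ds.adt, cfg.qc,
                                   cfg.adt_exclusion_list)
    out = workdir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    filtered = SimDataset(rna=rna, adt=adt, subject_meta=ds.subject_meta,
                          truth=ds.truth)
    write_dataset(filtered, out / "dataset")
    if manifest:
        manifest.record("qc", retained=rna.n_obs, removed=report.n_input - rna.n_obs,
                        genes=rna.n_vars, adt=(adt.n_vars if adt is not None else 0))


def _load_filtered(workdir: Path) -> SimDataset:
    return read_dataset(Path(workdir) / "qc" / "dataset")


def _norm_one_type(rna_t, adt_t, cfg: PipelineConfig):
    """VST → covariate regression → scale for RNA; CLR → regression → scale
    for ADT.  Returns (rna_scaled, rna_corrected, adt_scaled or None)."""
    vst = normalize.vst_residuals(rna_t, regularize=cfg.norm.vst_regularize)
    corrected = pd.DataFrame(vst.params["corrected_counts"],
                             index=vst.cells, columns=vst.features)
    if cfg.norm.regress_totals:
        tot = np.asarray(rna_t.X.sum(axis=1)).ravel()
        nfeat = rna_t.X.getnnz(axis=1)
        cov = pd.DataFrame({"log_total": np.log10(np.maximum(tot, 1)),
                            "log_nfeat": np.log10(np.maximum(nfeat, 1))},
                           index=rna_t.obs_names)
        vst = normalize.regress_covariates(vst, cov)
    rna_scaled = normalize.center_scale(vst)
    adt_scaled = None
    if adt_t is not None and adt_t.n_obs >= 2:
        clr = normalize.clr_normalize(adt_t, cfg.norm.clr_pseudocount)
        if cfg.norm.regress_totals:
            atot = np.asarray(adt_t.X.sum(axis=1)).ravel()
            anf = adt_t.X.getnnz(axis=1)
            acov = pd.DataFrame({"log_total": np.log10(np.maximum(atot, 1)),
                                 "log_nfeat": np.log10(np.maximum(anf, 1))},
                                index=adt_t.obs_names)
            clr = normalize.regress_covariates(clr, acov)
        adt_scaled = normalize.center_scale(clr)
    return rna_scaled, corrected, adt_scaled


def stage_normalize(workdir: Path, cfg: PipelineConfig,
                    manifest: RunManifest | None = None) -> None:
    workdir = Path(workdir)
    ds = _load_filtered(workdir)
    types = ds.rna.obs["cell_type"].astype(str)
    done = []
    for ct in sorted(types.unique()):
        mask = (types == ct).to_numpy()
        if mask.sum() < 10:
            log.warning("cell type %r has %d cells; normalization skipped",
                        ct, int(mask.sum()))
            continue
        rna_t = ds.rna[mask].copy()
        adt_t = None
        if ds.adt is not None:
            adt_cells = ds.adt.obs_names.intersection(rna_t.obs_names)
            if len(adt_cells) >= 2:
                adt_t = ds.adt[adt_cells].copy()
        rna_scaled, corrected, adt_scaled = _norm_one_type(rna_t, adt_t, cfg)
        d = workdir / "norm" / ct.replace("/", "_")
        _float_tsv(rna_scaled.to_frame(), d / "rna_scaled.tsv")
        _float_tsv(corrected, d / "rna_corrected.tsv")
        if adt_scaled is not None:
            _float_tsv(adt_scaled.to_frame(), d / "adt_scaled.tsv")
        done.append(ct)
    if manifest:
        manifest.record("normalize", cell_types=len(done))


def _norm_dirs(workdir: Path) -> dict[str, Path]:
    base = Path(workdir) / "norm"
    if not base.exists():
        return {}
    return {p.name: p for p in sorted(base.iterdir()) if p.is_dir()}


def stage_composition(workdir: Path, cfg: PipelineConfig,
                      manifest: RunManifest | None = None) -> None:
    workdir = Path(workdir)
    ds = _load_filtered(workdir)
    meta = ds.rna.obs.reset_index()
    table = comp.cell_type_proportions(meta)
    cohorts = ds.subject_meta["cohort"]
    tests = comp.compare_proportions(table, cohorts)
    out = workdir / "composition"
    _float_tsv(table.values, out / "proportions.tsv")
    _float_tsv(tests, out / "tests.tsv")
    if manifest:
        manifest.record("composition", groups=table.values.shape[1],
                        subjects=table.values.shape[0])


def stage_de(workdir: Path, cfg: PipelineConfig,
             manifest: RunManifest | None = None) -> None:
    workdir = Path(workdir)
    ds = _load_filtered(workdir)
    obs = ds.rna.obs
    results = []
    for ct, d in _norm_dirs(workdir).items():
        corrected = pd.read_csv(d / "rna_corrected.tsv", sep="\t", index_col=0)
        groups = obs.loc[corrected.index, "cohort"].astype(str)
        batches = obs.loc[corrected.index, "batch"].astype(str)
        try:
            res = diffexpr.de_genes(corrected, groups, alpha=cfg.de.alpha,
                                    min_lfc=cfg.de.min_lfc,
                                    min_cells=cfg.de.min_cells_per_group,
                                    cell_type=ct)
            res = diffexpr.flag_batch_artifacts(res, corrected, groups, batches,
                                                alpha=cfg.de.alpha,
                                                min_effect=cfg.de.min_lfc)
            results.append(res)
        except ValueError as e:
            log.warning("DE genes skipped for %r: %s", ct, e)
        adt_path = d / "adt_scaled.tsv"
        if adt_path.exists():
            scaled = pd.read_csv(adt_path, sep="\t", index_col=0)
            agroups = obs.loc[scaled.index, "cohort"].astype(str)
            abatches = obs.loc[scaled.index, "batch"].astype(str)
            try:
                res = diffexpr.de_proteins(scaled, agroups, alpha=cfg.de.alpha,
                                           min_diff=cfg.de.min_diff,
                                           min_cells=cfg.de.min_cells_per_group,
                                           cell_type=ct)
                res = diffexpr.flag_batch_artifacts(res, scaled, agroups,
                                                    abatches,
                                                    alpha=cfg.de.alpha,
                                                    min_effect=cfg.de.min_diff)
                results.append(res)
            except ValueError as e:
                log.warning("DE proteins skipped for %r: %s", ct, e)
    table = (pd.concat(results, ignore_index=True) if results
             else pd.DataFrame(columns=diffexpr.DE_COLUMNS))
    _float_tsv(table, Path(workdir) / "de" / "results.tsv")
    if manifest:
        manifest.record("de", tests=len(table),
                        significant=int(table["significant"].sum())
                        if len(table) else 0)


def stage_cluster(workdir: Path, cfg: PipelineConfig,
                  manifest: RunManifest | None = None) -> None:
    from . import cluster as cl

    workdir = Path(workdir)
    if not cfg.cluster.target_cell_types:
        if manifest:
            manifest.record("cluster", skipped=True)
        return
    ds = _load_filtered(workdir)
    obs = ds.rna.obs
    seed = stage_seed(cfg.seed, "cluster")
    n_found = 0
    for ct in cfg.cluster.target_cell_types:
        d = _norm_dirs(workdir).get(ct.replace("/", "_"))
        if d is None:
            log.warning("no normalized matrix for cluster target %r", ct)
            continue
        frame = pd.read_csv(d / "rna_scaled.tsv", sep="\t", index_col=0)
        m = normalize.NormalizedMatrix(frame.to_numpy(), frame.index,
                                       frame.columns, "scaled")
        batches = obs.loc[m.cells, "batch"].astype(str)
        feats = cl.select_variable_features(m, batches,
                                            cfg.cluster.n_variable_features)
        sub = normalize.NormalizedMatrix(
            m.to_frame()[feats].to_numpy(), m.cells, pd.Index(feats), m.method)
        std = cl.batch_standardize(sub, batches)
        scores, _, _ = cl.pca_embed(std, cfg.cluster.n_pcs)
        graph = cl.snn_graph(scores, cfg.cluster.k_neighbors, cfg.cluster.prune)
        result = cl.louvain_cluster(graph, cfg.cluster.resolution, seed,
                                    embedding=scores)
        labels = pd.DataFrame({"barcode": m.cells,
                               "cluster": result.labels.to_numpy()})
        meta = obs.loc[m.cells, ["subject", "cohort"]].reset_index()
        overrep = cl.cluster_overrepresentation(result, meta)
        safe = ct.replace("/", "_")
        out = workdir / "cluster"
        out.mkdir(parents=True, exist_ok=True)
        labels.to_csv(out / f"{safe}_clusters.tsv", sep="\t", index=False)
        _float_tsv(overrep, out / f"{safe}_overrep.tsv")
        n_found += result.n_clusters
    if manifest:
        manifest.record("cluster", targets=len(cfg.cluster.target_cell_types),
                        clusters=n_found)


def stage_enrich(workdir: Path, cfg: PipelineConfig,
                 manifest: RunManifest | None = None) -> None:
    from . import enrich as en

    workdir = Path(workdir)
    if not cfg.gmt_collections:
        if manifest:
            manifest.record("enrich", skipped=True)
        return
    de = pd.read_csv(workdir / "de" / "results.tsv", sep="\t", index_col=0)
    rna = de[de["modality"] == "RNA"]
    n_out = 0
    for name, path in cfg.gmt_collections.items():
        coll = en.read_gmt(path, name)
        for ct, rows in rna.groupby("cell_type", observed=True):
            query = set(rows.loc[rows["significant"], "feature"])
            background = set(rows["feature"])
            if not query:
                continue
            res = en.enrich_hypergeometric(query, coll, background)
            safe = str(ct).replace("/", "_")
            _float_tsv(res, workdir / "enrich" / f"{name}_{safe}.tsv")
            n_out += len(res)
    if manifest:
        manifest.record("enrich", results=n_out)


def stage_ml(workdir: Path, cfg: PipelineConfig,
             manifest: RunManifest | None = None) -> dict:
    workdir = Path(workdir)
    ds = _load_filtered(workdir)
    if cfg.ml.explicit_features:
        de = pd.DataFrame(
            [dict(zip(("cell_type", "modality", "feature"),
                      fid.split(mlpipe.FEATURE_SEP)), significant=True)
             for fid in cfg.ml.explicit_features])
    else:
        de = pd.read_csv(workdir / "de" / "results.tsv", sep="\t", index_col=0)
    if not de["significant"].any():
        log.warning("no significant DE features; ML stage skipped")
        if manifest:
            manifest.record("ml", skipped=True)
        return {}
    scaled_expr: dict = {}
    for ct, d in _norm_dirs(workdir).items():
        scaled_expr[(ct, "RNA")] = pd.read_csv(d / "rna_scaled.tsv", sep="\t",
                                               index_col=0)
        adt_path = d / "adt_scaled.tsv"
        if adt_path.exists():
            scaled_expr[(ct, "ADT")] = pd.read_csv(adt_path, sep="\t",
                                                   index_col=0)
    labels = ds.subject_meta["cohort"]
    cell_subjects = ds.rna.obs["subject"].astype(str)
    matrix = mlpipe.build_feature_matrix(scaled_expr, de, cell_subjects, labels)
    seed = stage_seed(cfg.seed, "ml")
    result = mlpipe.run_ml(matrix, n_top=cfg.ml.n_top, seed=seed,
                           roster_names=cfg.ml.roster, folds=cfg.ml.cv_folds,
                           repeats=cfg.ml.cv_repeats,
                           positive=cfg.ml.positive_label,
                           train_fraction=cfg.ml.train_fraction)
    out = workdir / "ml"
    out.mkdir(parents=True, exist_ok=True)
    _float_tsv(matrix.values, out / "feature_matrix.tsv")
    _float_tsv(result["selection_table"], out / "selection.tsv")
    (out / "model_report.json").write_text(
        json.dumps({"best_model": result["best_model"],
                    "best_auroc": result["best_auroc"],
                    "selected_features": result["selected_features"],
                    "train_subjects": result["train_subjects"],
                    "test_subjects": result["test_subjects"],
                    "models": result["report"]}, indent=1, default=str))
    if manifest:
        manifest.record("ml", features=matrix.values.shape[1],
                        best_model=result["best_model"],
                        best_auroc=round(result["best_auroc"], 6))
    return result


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, workdir: str | Path,
                 simcfg: SimConfig | None = None,
                 dataset_dir: str | Path | None = None) -> RunManifest:
    """Run all stages on a work directory.

    Either ``simcfg`` (simulate a cohort) or ``dataset_dir`` (copy in an
    existing 10x-style dataset directory) must be given.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed,
                           stage_seeds={s: stage_seed(cfg.seed, s)
                                        for s in STAGES})
    (workdir / "config.yaml").write_text(cfg.to_yaml())
    if simcfg is not None:
        stage_simulate(simcfg, workdir, manifest)
    elif dataset_dir is not None:
        ds = read_dataset(dataset_dir)
        write_dataset(ds, workdir / "dataset")
        manifest.record("read", cells=ds.rna.n_obs)
    else:
        raise ValueError("need simcfg or dataset_dir")
    stage_qc(workdir, cfg, manifest)
    stage_normalize(workdir, cfg, manifest)
    stage_composition(workdir, cfg, manifest)
    stage_de(workdir, cfg, manifest)
    stage_cluster(workdir, cfg, manifest)
    stage_enrich(workdir, cfg, manifest)
    stage_ml(workdir, cfg, manifest)
    manifest.save(workdir / "manifest.json")
    return manifest
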