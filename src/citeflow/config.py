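"""Pipeline configuration.

Every numeric threshold the analysis uses lives here, with the study's
values as defaults; stage code reads them from the config rather than
hard-coding them.  A single master seed fans out to per-stage seeds by a
declared deterministic derivation (CRC32 of the stage name folded into the
master seed), so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, asdict, is_dataclass
from typing import Any

import yaml


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the master seed and the stage name.

    Deterministic, stable across platforms, and always in [0, 2**31).
    """
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class QcThresholds:
    """Cell-retention thresholds.

    Field order defines the first-failing-rule attribution order in QC
    reports.  UMI bounds are inclusive on both ends; the isotype rule is
    strict (< max_pct_isotype).
    """

    umi_min: int = 500
    umi_max: int = 10_000
    min_genes: int = 200
    max_pct_mito: float = 15.0
    max_pct_ribo: float = 60.0
    max_adt_features: int = 260
    max_pct_isotype: float = 2.0

    def __post_init__(self) -> None:
        if not self.umi_min < self.umi_max:
            raise ValueError("umi_min must be < umi_max")
        for name in ("max_pct_mito", "max_pct_ribo", "max_pct_isotype"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")

    # rule order used for first-failing attribution
    RULES = (
        "umi_min",
        "umi_max",
        "min_genes",
        "max_pct_mito",
        "max_pct_ribo",
        "max_adt_features",
        "max_pct_isotype",
    )


@dataclass
class NormConfig:
    """Normalization dialect flags."""

    clr_pseudocount: float = 1.0
    vst_regularize: bool = True
    regress_totals: bool = True  # regress log totals / log feature counts
    rna_scaling_factor: float = 1e7  # subject-level log profile, RNA
    adt_scaling_factor: float = 5e5  # subject-level log profile, ADT


@dataclass
class DEConfig:
    alpha: float = 0.05
    min_lfc: float = 0.20  # |log2 FC| gate for genes
    min_diff: float = 0.20  # |mean scaled difference| gate for proteins
    min_cells_per_group: int = 3
    use_corrected_counts: bool = True  # NB test on VST corrected counts


@dataclass
class ClusterConfig:
    n_variable_features: int = 3000
    n_pcs: int = 30
    k_neighbors: int = 20
    prune: float = 1.0 / 15.0
    resolution: float = 0.6
    target_cell_types: tuple[str, ...] = ()  # empty → skip clustering stage


@dataclass
class MLConfig:
    n_top: int = 20
    train_fraction: float = 0.5
    cv_folds: int = 5
    cv_repeats: int = 2
    roster: tuple[str, ...] = (
        "glm",
        "lda",
        "glmnet",
        "knn",
        "cart",
        "rf",
        "svmRadial",
        "nb",
        "avNNet",
    )
    positive_label: str = "AS"
    # "cell_type|modality|feature" ids to use instead of the DE-significant
    # set, decoupling the ML stage from the DE stage
    explicit_features: tuple[str, ...] = ()


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults reproduce the study settings."""

    qc: QcThresholds = field(default_factory=QcThresholds)
    norm: NormConfig = field(default_factory=NormConfig)
    de: DEConfig = field(default_factory=DEConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    ml: MLConfig = field(default_factory=MLConfig)
    adt_exclusion_list: tuple[str, ...] = ()
    gmt_collections: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kw: dict[str, Any] = {}
        for key, sub in (
            ("qc", QcThresholds),
            ("norm", NormConfig),
            ("de", DEConfig),
            ("cluster", ClusterConfig),
            ("ml", MLConfig),
        ):
            if key in d:
                sd = dict(d.pop(key))
                for k, v in list(sd.items()):
                    if isinstance(v, list):
                        sd[k] = tuple(v)
                kw[key] = sub(**sd)
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kw[k] = v
        return cls(**kw)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:16]


def _plain(obj: Any) -> Any:
    """Recursively convert tuples/dataclasses to YAML-safe plain types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
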