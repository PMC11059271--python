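"""Pipeline configuration: every threshold in one place, YAML-loadable.

Defaults reproduce the published analysis thresholds exactly; unknown keys in
a config file are rejected rather than silently ignored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # DMR calling
    dmr_diff_threshold: float = 0.4
    dmr_hypo_threshold: float = 0.3
    dmr_hyper_threshold: float = 0.7
    dmr_mode: str = "absolute"  # or "normal_minus_tumor"
    min_coverage: int = 1
    # DEG selection
    deg_min_abs_lfc: float = 2.0
    deg_max_padj: float = 0.05
    deg_min_basemean: float = 100.0
    # gene scoring
    gene_min_cpgs: int = 10
    gene_min_fraction: float = 0.5
    count_indeterminate_as_dmr: bool = True
    top_n: int = 10
    # cohort
    specificity_threshold: float = 0.4
    specificity_mode: str = "per_class"  # or "pooled"
    extreme_delta: float = 0.8
    tsne_k: int = 10_000
    tsne_perplexity: float = 30.0
    run_tsne: bool = True
    # methylation-expression fit
    expr_scale: str = "normalized"  # or "log", "fpkm"
    fpkm_center_mode: str = "center"  # or "mean_minus_value"
    # variant / TMB / CNV / fusion
    variant_min_depth: int = 10
    variant_max_af: float = 0.01
    variant_regions: tuple = ("exonic", "splicing")
    missing_af_passes: bool = True
    coding_length_mb: float = 30.0
    cnv_del_threshold: float = -0.4
    cnv_amp_threshold: float = 0.3
    # orchestration
    seed: int = 0
    out_dir: str = "methomics_out"
    # inputs
    tumor_reports: list = field(default_factory=list)
    normal_reports: list = field(default_factory=list)
    gene_map: str | None = None
    fpkm: str | None = None
    de_table: str | None = None
    links: str | None = None
    beta_matrix: str | None = None
    beta_labels: str | None = None
    target_class: str | None = None
    reference_class: str | None = None
    variants: str | None = None
    fusions: str | None = None
    coding_genes: str | None = None
    log2_table: str | None = None

    def validate(self) -> None:
        if self.dmr_mode not in ("absolute", "normal_minus_tumor"):
            raise ConfigError(f"dmr_mode: unknown value {self.dmr_mode!r}")
        if self.specificity_mode not in ("per_class", "pooled"):
            raise ConfigError(f"specificity_mode: unknown value {self.specificity_mode!r}")
        if self.expr_scale not in ("normalized", "log", "fpkm"):
            raise ConfigError(f"expr_scale: unknown value {self.expr_scale!r}")
        if self.fpkm_center_mode not in ("center", "mean_minus_value"):
            raise ConfigError(f"fpkm_center_mode: unknown value {self.fpkm_center_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; CLI overrides beat the file, the file beats defaults."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {unknown}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if isinstance(cfg.variant_regions, list):
            cfg.variant_regions = tuple(cfg.variant_regions)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant_regions"] = list(self.variant_regions)
        return d

    def config_hash(self) -> str:
        return hashlib.md5(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
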