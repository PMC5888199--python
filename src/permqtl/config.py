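"""Pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import HLA_REGION
from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    Threshold defaults mirror the analysis conventions: strict call-rate /
    MAF / INFO exclusions below 0.98 / 0.01 / 0.8, LD proxies at r^2 >= 0.8
    within a 1-Mb search window, a 4-Mb cis window, 10,000 permutation
    replicates with alpha levels 5% and 10%.
    """

    genotypes: str = ""
    expression: str = ""
    probe_annotation: str = ""
    metadata: str = ""
    index_snps: str = ""
    out_dir: str = "permqtl_out"

    min_call_rate: float = 0.98
    min_maf: float = 0.01
    min_info: float = 0.8
    region_blacklist: list = field(default_factory=lambda: [list(HLA_REGION)])
    quality_blacklist: list = field(default_factory=list)
    probe_blacklist: list = field(default_factory=list)

    r2_min: float = 0.8
    search_window_bp: int = 1_000_000
    cis_window_bp: int = 4_000_000

    normalize_method: str = "log-quantile"
    batch_column: str = "batch"

    permutations: int = 10_000
    alphas: list = field(default_factory=lambda: [0.05, 0.10])
    seed: int | None = None

    covariates: list = field(default_factory=lambda: ["age", "sex", "crp", "sjc"])
    delta_tolerance: float = 0.1

    def validate(self) -> "PipelineConfig":
        if self.seed is None:
            raise ConfigurationError("seed is mandatory (permutation stage is stochastic)")
        if not (0 < self.min_call_rate <= 1):
            raise ConfigurationError("min_call_rate must be in (0, 1]")
        if not (0 <= self.min_maf <= 0.5):
            raise ConfigurationError("min_maf must be in [0, 0.5]")
        if not (0 <= self.min_info <= 1):
            raise ConfigurationError("min_info must be in [0, 1]")
        if not (0 <= self.r2_min <= 1):
            raise ConfigurationError("r2_min must be in [0, 1]")
        if not all(0 < a <= 1 for a in self.alphas):
            raise ConfigurationError("alpha levels must be in (0, 1]")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path
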