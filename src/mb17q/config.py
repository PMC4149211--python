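"""Configuration objects for simulation and pipeline runs.

All genomic coordinates in this package are 1-based (VCF convention).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration field is out of its documented range."""


# chromosome 17 is ~81.2 Mb (GRCh37/38 agree to within a Mb)
CHR17_LENGTH = 81_200_000

#: Default isodicentric breakpoint coordinate (17p11.2 proximal arm).
DEFAULT_BREAKPOINT = 20_000_000


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generators.

    The defaults emulate the structure of an amplification-based FFPE
    sequencing study of 57 tumors and a 103-tumor expression cohort:
    sparse true somatic variants present in every amplification replicate
    at allele fraction 0.2-0.6, abundant per-replicate FFPE artifacts
    biased toward C>T/G>A deamination changes, hemizygous (~0.5x) and
    duplicated (~1.5x) dosage compartments on chromosome 17 in
    i17q-positive samples, and exponential survival with risk-group
    hazards matching ~86%/40% five-year overall survival.
    """

    # --- variant simulation ---
    n_samples: int = 57
    n_replicates_per_sample: int = 2
    true_variant_rate: float = 0.23  # expected true variants per sample
    artifact_rate: float = 5.0  # expected artifact calls per replicate
    true_af_range: tuple[float, float] = (0.2, 0.6)
    #: (alpha, beta, scale) of a scaled Beta over (0, scale]; right-skewed so
    #: most artifacts sit well below the 0.20 caller threshold but some pass.
    artifact_af_beta: tuple[float, float, float] = (1.0, 4.0, 0.3)
    #: number of distinct targetable positions in the amplicon panel
    #: (192 amplicons x ~250 bp)
    n_target_positions: int = 48_000

    # --- expression simulation ---
    n_features: int = 1000
    n_chr17_features: int = 260
    breakpoint: int = DEFAULT_BREAKPOINT
    hemizygous_fold: float = 0.5
    duplicated_fold: float = 1.5
    focal_excess_log2: float = 0.0  # extra log2 suppression of the focal gene
    focal_gene: str = "TP53"
    i17q_fraction: float = 0.30
    noise_sd: float = 0.25  # log2-scale Gaussian noise
    baseline_mean: float = 8.0  # log2 microarray-like baseline
    baseline_sd: float = 1.5
    group4_prob: float = 0.85  # P(group4 | i17q+); remainder go to group3
    max_probes: int = 10

    # --- survival simulation ---
    hazard_by_group: dict[str, float] = field(
        default_factory=lambda: {"SR": 0.0025, "HR": 0.0153}  # events / month
    )
    hr_fraction: float = 0.4
    dfs_hazard_multiplier: float = 1.6  # relapse hazard relative to death
    censor_time: float = 120.0  # months

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def bad(name: str, why: str) -> ConfigError:
            return ConfigError(f"invalid SimConfig field {name!r}: {why}")

        if self.n_samples < 1:
            raise bad("n_samples", "must be >= 1")
        if self.n_replicates_per_sample < 2:
            raise bad("n_replicates_per_sample", "must be >= 2")
        for name in ("true_variant_rate", "artifact_rate"):
            if getattr(self, name) < 0:
                raise bad(name, "rates must be >= 0")
        lo, hi = self.true_af_range
        if not (0.2 <= lo <= hi <= 0.6):
            raise bad("true_af_range", "must be an interval within [0.2, 0.6]")
        a, b, scale = self.artifact_af_beta
        if a <= 0 or b <= 0 or not (0 < scale <= 0.3):
            raise bad("artifact_af_beta", "shape > 0 and 0 < scale <= 0.3")
        if self.n_target_positions < 1:
            raise bad("n_target_positions", "must be >= 1")
        if not 0 < self.n_chr17_features <= self.n_features:
            raise bad("n_chr17_features", "must be in (0, n_features]")
        if not 1 <= self.breakpoint <= CHR17_LENGTH:
            raise bad("breakpoint", f"must lie in [1, {CHR17_LENGTH}]")
        if not self.hemizygous_fold < 1 < self.duplicated_fold:
            raise bad(
                "hemizygous_fold/duplicated_fold",
                "requires hemizygous_fold < 1 < duplicated_fold",
            )
        if not 0 < self.i17q_fraction < 1:
            raise bad("i17q_fraction", "must be in (0, 1)")
        if self.noise_sd < 0:
            raise bad("noise_sd", "must be >= 0")
        if not 0 <= self.group4_prob <= 1:
            raise bad("group4_prob", "must be in [0, 1]")
        if not self.hazard_by_group:
            raise bad("hazard_by_group", "must name at least one stratum")
        for grp, lam in self.hazard_by_group.items():
            if lam <= 0:
                raise bad("hazard_by_group", f"hazard for {grp!r} must be > 0")
        if self.censor_time < 0:
            raise bad("censor_time", "must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["true_af_range"] = list(self.true_af_range)
        d["artifact_af_beta"] = list(self.artifact_af_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "true_af_range" in d:
            d["true_af_range"] = tuple(d["true_af_range"])
        if "artifact_af_beta" in d:
            d["artifact_af_beta"] = tuple(d["artifact_af_beta"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: input paths, thresholds, outputs."""

    pooled_variants: str | None = None
    replicate_variants: list[str] = field(default_factory=list)
    truth_table: str | None = None
    expression: str | None = None
    feature_meta: str | None = None
    sample_meta: str | None = None
    clinical: str | None = None
    gene_panel: str | None = None

    cohort_size: int = 57
    min_qual: float = 30.0
    min_mapq: float = 30.0
    min_af: float = 0.20
    min_replicate_af: float = 0.05
    max_pop_af: float = 0.01
    breakpoint: int = DEFAULT_BREAKPOINT
    focal_gene: str = "TP53"
    alpha: float = 0.05
    bonferroni_mode: str = "hemizygous"  # or "chr17"
    seed: int = 0
    output_dir: str = "mb17q_out"

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_mapq"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("min_af", "min_replicate_af", "max_pop_af", "alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.bonferroni_mode not in ("hemizygous", "chr17"):
            raise ConfigError("bonferroni_mode must be 'hemizygous' or 'chr17'")
        if self.cohort_size < 1:
            raise ConfigError("cohort_size must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
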