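"""Typed pipeline configuration with YAML loading and strict validation."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, with paper-default values.

    Unknown keys, wrong types and out-of-range values are rejected with
    a message listing all violations at once.
    """

    # inputs
    counts_tsv: str | None = None
    kraken_dir: str | None = None
    metadata_tsv: str | None = None
    annotation_tsv: str | None = None
    phenotype_tsv: str | None = None
    coverage_inputs: list = field(default_factory=list)
    outdir: str = "bloodsift_out"
    seed: int = 0

    # profiles
    min_total_reads: int = 100
    ra_threshold: float = 0.005
    count_threshold: int = 10
    presence_rule: str = "both"

    # decontam
    batch_variables: list | None = None
    min_batch_size: int = 100
    prev_threshold: float = 0.25
    prev_fold: float = 2.0
    rho_threshold: float = 0.7
    excluded_variables: list = field(default_factory=lambda: ["library_kit"])
    min_max_reads: int = 100
    zero_replacement_factor: float = 0.65

    # enrichment
    enrichment_iters: int = 1000

    # networks
    network_thresholds: list = field(default_factory=lambda: [0.05, 0.2, 0.3])
    cohort_network_threshold: float = 0.2
    excluded_cohorts: list = field(default_factory=list)
    pooled_excludes_cohorts: bool = False
    sparcc_exclusion_iters: int = 10
    sparcc_exclusion_threshold: float = 0.1
    sparcc_pseudocount: float = 1.0
    sparcc_draws: int = 20

    # replication
    bin_size: int = 10000
    median_window_bins: int = 11
    skew_window: int = 10000
    min_assigned_reads: int = 1000
    ptr_threshold: float = 1.1

    # association screen
    min_present: int = 50
    alpha: float = 0.05

    # stage toggles
    run_decontam: bool = True
    run_enrichment: bool = True
    run_networks: bool = True
    run_replication: bool = True
    run_assoc: bool = True

    def validate(self) -> None:
        problems = []
        ranges = {
            "ra_threshold": (0.0, 1.0), "prev_threshold": (0.0, 1.0),
            "rho_threshold": (0.0, 1.0), "alpha": (0.0, 1.0),
            "sparcc_exclusion_threshold": (0.0, 1.0),
            "zero_replacement_factor": (0.0, 1.0),
            "cohort_network_threshold": (0.0, 1.0),
        }
        for name, (lo, hi) in ranges.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                problems.append(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("min_total_reads", "count_threshold", "min_batch_size",
                     "min_max_reads", "enrichment_iters", "bin_size",
                     "median_window_bins", "skew_window", "min_assigned_reads",
                     "min_present", "sparcc_draws", "sparcc_exclusion_iters"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                problems.append(f"{name}={v!r} must be a non-negative integer")
        if self.presence_rule not in ("both", "either"):
            problems.append(f"presence_rule={self.presence_rule!r} not in "
                            "('both', 'either')")
        if self.prev_fold < 1.0:
            problems.append(f"prev_fold={self.prev_fold} must be >= 1")
        if self.ptr_threshold < 1.0:
            problems.append(f"ptr_threshold={self.ptr_threshold} must be >= 1")
        for t in self.network_thresholds:
            if not (0.0 <= t < 1.0):
                problems.append(f"network threshold {t} outside [0, 1)")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(path_or_dict) -> PipelineConfig:
    """Load and validate a YAML config file (or dict) into PipelineConfig.

    An empty file yields the all-defaults configuration; unknown keys
    are rejected by name.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path_or_dict}: config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
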