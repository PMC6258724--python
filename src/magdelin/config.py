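"""Run configuration: thresholds, seed, input paths.

The config file is a flat YAML mapping (key: value, no nesting).  Every
stochastic operation in a run derives its random stream from the single
``seed``; the CLI flag ``--seed`` overrides the file value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from magdelin.types import ValidationError


@dataclass
class RunConfig:
    # lineage delineation: collapse clades whose mean pairwise patristic
    # distance (substitutions/site) is below this
    collapse_threshold: float = 0.6
    # bin curation: relative deviation from the bin mean above which a
    # contig's GC or abundance is an outlier
    outlier_rel_threshold: float = 0.25
    # 'relative' -> |x - mean| / mean; 'absolute' -> |x - mean| (the
    # absolute-points alternative, mainly meaningful for GC)
    outlier_rule: str = "relative"
    # MAG quality gate, both bounds strict
    completeness_gate: float = 50.0
    contamination_gate: float = 10.0
    # AAI best-hit filters (%)
    min_identity: float = 30.0
    min_coverage: float = 70.0
    # gap penalties for local protein alignment (gap of length k costs
    # gap_open + (k - 1) * gap_extend)
    gap_open: int = 11
    gap_extend: int = 1
    # floor on best cross-group AAI below which a singleton group is still
    # called novel (confirmed-weak)
    singleton_aai_floor: float = 50.0
    # gene presence tiers: absent < tier_partial <= partial < tier_core <= core
    tier_partial: float = 0.30
    tier_core: float = 0.50
    seed: int = 0
    # input paths (any may be None when the stage is driven by `simulate`)
    bins_dir: Optional[str] = None
    proteomes_dir: Optional[str] = None
    tree_path: Optional[str] = None
    query_ids_path: Optional[str] = None
    counts_path: Optional[str] = None
    annotations_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    markers_path: Optional[str] = None
    marker_set_path: Optional[str] = None
    clusters_path: Optional[str] = None
    sites_path: Optional[str] = None
    libsizes_path: Optional[str] = None
    core_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        import math

        for name in (
            "collapse_threshold",
            "outlier_rel_threshold",
            "completeness_gate",
            "contamination_gate",
            "min_identity",
            "min_coverage",
            "gap_open",
            "gap_extend",
            "tier_partial",
            "tier_core",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"threshold {name}={value} must be finite and >= 0")
        if self.tier_partial >= self.tier_core:
            raise ValidationError(
                f"presence tier lower bound {self.tier_partial} must be below "
                f"upper bound {self.tier_core}"
            )
        if self.outlier_rule not in ("relative", "absolute"):
            raise ValidationError(f"unknown outlier_rule {self.outlier_rule!r}")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")
        self.seed = int(self.seed)


def load_config(path: str | Path, seed_override: Optional[int] = None) -> RunConfig:
    """Read a flat YAML config file; unknown keys are rejected."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"config {path}: unknown keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    if seed_override is not None:
        cfg.seed = int(seed_override)
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)
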