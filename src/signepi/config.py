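"""Analysis configuration: every threshold of the discovery/validation procedure.

All defaults are the published thresholds of the breeding-program screen:
markers with minor allele frequency below 0.01, more than 20% missing calls
or more than 20% heterozygotes are dropped by the genotyping pipeline; the
discovery screen keeps markers with MAF > 0.3, retains marker pairs with
r^2 > 0.9 inside individual families, r^2 > 0.8 on the pooled families, and
requires the pair to pass in at least two families.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds of the sign-epistasis discovery and validation procedure.

    Fractions are in [0, 1]; ``r2_family`` must not be below ``r2_combined``
    (the family screen is the stricter first stage of the two-stage design).
    """

    # genotyping-pipeline marker filters
    maf_min_pipeline: float = 0.01
    max_missing: float = 0.20
    max_het: float = 0.20
    # discovery screen
    maf_min_discovery: float = 0.30
    r2_family: float = 0.9
    r2_combined: float = 0.8
    min_families: int = 2
    maf_per_family: bool = False  # evaluate the discovery MAF screen per family instead of pooled
    average_family_mode: bool = False  # pass pairs on mean per-family r2 instead of per-family counts
    # Residual heterozygous calls in mostly-inbred lines are phase-ambiguous and
    # often genotyping errors; LD screens treat them as missing by default.
    ld_het_as_missing: bool = True
    # flanking-window / block analysis
    n_flank_per_side: int = 20
    block_r2: float = 0.5
    block_min_run: int = 3
    # validation rules
    opposite_min_share: float = 0.10
    fixation_threshold: float = 0.95
    het_inconclusive_share: float = 0.30
    # region grouping and QC
    region_gap_bp: int = 10_000_000
    outlier_sd: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "maf_min_pipeline",
            "max_missing",
            "max_het",
            "maf_min_discovery",
            "r2_family",
            "r2_combined",
            "opposite_min_share",
            "fixation_threshold",
            "het_inconclusive_share",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {value!r}")
        if self.r2_family < self.r2_combined:
            raise ValueError(
                "r2_family must be >= r2_combined (family screen is the stricter stage)"
            )
        if self.min_families < 2:
            raise ValueError("min_families must be at least 2")
        for name in ("n_flank_per_side", "block_min_run", "region_gap_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
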