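"""Pipeline configuration: every stage threshold in one round-trippable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds for the full replicate-integrated detection cascade.

    Defaults are the operating point of the published workflow this
    package models: 2/3 consensus concordance, family size >= 2, a
    99%-critical-value Z threshold, >3 nonreference alleles per
    replicate, a five-fold CHIP rule, a 1% tumor-catalog VAF floor and a
    <=3-allele "absent" rule for the tumor-informed search.
    """

    concordance: float = 0.66
    min_family_size: int = 2
    z_min: float = 2.576
    z_cap: float = 100.0
    min_nra_per_rep: int = 4       # i.e. NRA > 3 in each replicate
    chip_fold: float = 5.0
    chip_strict: bool = False
    tumor_min_vaf: float = 0.01
    absent_threshold: int = 3      # combined NRA <= this is scored absent
    fisher_side: str = "greater"
    tissue: str = "pancreas"
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.concordance < 1.0:
            raise ValueError("concordance must be in (0, 1)")
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")
        if self.min_nra_per_rep < 1:
            raise ValueError("min_nra_per_rep must be >= 1")
        if self.chip_fold < 1:
            raise ValueError("chip_fold must be >= 1")
        if not 0.0 <= self.tumor_min_vaf <= 1.0:
            raise ValueError("tumor_min_vaf must be a fraction")
        if self.absent_threshold < 0:
            raise ValueError("absent_threshold must be >= 0")
        if self.fisher_side not in ("greater", "less", "two-sided"):
            raise ValueError("fisher_side must be greater/less/two-sided")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
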