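"""Run configuration: every pipeline threshold with its default, YAML-loadable.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # read QC
    quality_offset: int = 33
    max_barcode_mismatch: int = 0
    min_read_length: int = 100
    # individual-level calling
    prior: float = 1e-4  # prior probability of heterozygosity (mutation rate)
    lrt_alpha: float = 0.05
    lrt_null: str = "chi2"  # or "mixture"
    lrt_rejection_to_hom: bool = True
    # population-level detection
    reps: int = 10_000  # error-null replicates
    alpha: float = 0.001  # right-tail probability for the critical value
    second_mode: str = "second_allele"  # or "all_nonmajor"
    filter_mode: str = "conservative"  # or "literal"
    min_indiv_2x: int = 3
    proximity_bp: int = 5
    max_het_fraction: float = 0.90
    # genotype-matrix QC and popgen
    min_call_rate: float = 0.90
    max_low_prob_fraction: float = 0.50
    max_missing: float = 0.05  # per-analysis-group missingness cap (0.05 / 0.10)
    het_excess_threshold: float = 0.60
    f_mode: str = "multilocus"
    n_perm: int = 10_000
    mantel_perm: int = 10_000
    hwe_alpha: float = 0.05
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.lrt_null not in ("chi2", "mixture"):
            raise ValueError("lrt_null must be 'chi2' or 'mixture'")
        if self.second_mode not in ("second_allele", "all_nonmajor"):
            raise ValueError("second_mode must be 'second_allele' or 'all_nonmajor'")
        if self.filter_mode not in ("conservative", "literal"):
            raise ValueError("filter_mode must be 'conservative' or 'literal'")
        for name in ("min_call_rate", "max_low_prob_fraction", "max_missing",
                     "het_excess_threshold", "max_het_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
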