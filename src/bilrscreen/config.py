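"""Run configuration: the single source of truth for every threshold.

Defaults equal the study's published values: fluorescence ratio 5, HMM
E-value 1e-100, 50% reference-length fraction, HGDR motif, 5 CPM presence
threshold, one-million-read QC floor, 30-day age bins over the first year,
and a 3-year minimum age for the healthy-adult cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # assay
    ratio_threshold: float = 5.0
    # comparative screen
    min_score_ratio: float = 0.3
    min_ec_members: int = 3
    ec_all_members: bool = False
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # profile HMM
    evalue_max: float = 1e-100
    min_length_fraction: float = 0.5
    motif: str = "HGDR"
    motif_mode: str = "columns"
    calibration_n: int = 300
    calibration_length: int = 400
    # metagenome profiling
    cpm_threshold: float = 5.0
    min_reads: int = 1_000_000
    host_k: int = 31
    map_k: int = 21
    min_identity: float = 0.9
    min_shared_fraction: float = 0.5
    cpm_denominator: str = "post_host"
    age_bin_days: int = 30
    age_range_days: int = 365
    healthy_min_age_days: int = 3 * 365
    continuity_correction: bool = True
    # shared
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        positive = (
            "ratio_threshold", "min_score_ratio", "min_ec_members", "evalue_max",
            "min_length_fraction", "cpm_threshold", "min_reads", "host_k",
            "map_k", "min_identity", "age_bin_days", "age_range_days",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cpm_denominator not in ("post_host", "raw"):
            raise ValueError("cpm_denominator must be 'post_host' or 'raw'")
        if self.motif_mode not in ("columns", "regex"):
            raise ValueError("motif_mode must be 'columns' or 'regex'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
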