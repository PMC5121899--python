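"""Pipeline configuration: every tunable threshold in one place.

Defaults follow the curation protocol: knockdown filter log2FC < -0.5,
hairpin free energy < -22 kcal/mol, more than 16 mature/star pairs, 2-nt
3' overhangs, homology rule of >=19 aligned columns with <=1 mismatch,
co-mature arm ratio < 2, target duplex energy <= -12 kcal/mol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # expression / knockdown filter
    fc_threshold: float = -0.5
    pseudocount: float = 0.25
    arm_tolerance: int = 2  # 5'-end wobble for arm assignment, nt
    negctrl_max_len: int = 500
    negctrl_min_cov: int = 10
    # structure
    energy_max: float = -22.0
    min_pairs: int = 17  # "more than 16 nucleotides paired"
    overhang: int = 2
    overhang_tol: int = 0
    loop_min: int = 8
    loop_max: int = 40
    fold_backend: str = "internal"
    # curation
    homogeneity_threshold: float = 0.66
    comature_ratio: float = 2.0
    align_min_cols: int = 19  # "alignment longer than 18 nucleotides"
    align_max_mismatch: int = 1
    artifact_flank: int = 50
    seed_start: int = 2  # 1-based, inclusive
    seed_end: int = 7
    species_code: str = "bg"
    # targets
    target_energy: float = -12.0
    # comparative
    cluster_max_gap: int = 20_000  # bp
    # report
    report_flank: int = 30
    report_read_min: int = 18
    report_read_max: int = 26

    @property
    def seed_positions(self) -> tuple[int, int]:
        return (self.seed_start, self.seed_end)

    @property
    def loop_range(self) -> tuple[int, int]:
        return (self.loop_min, self.loop_max)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
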