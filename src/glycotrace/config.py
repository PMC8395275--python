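"""Run configuration, loadable from TOML.

Defaults reflect the acquisition and search settings the pipeline was
built around: precursor tolerance 6 ppm, fragment tolerance 20 mmu,
precursor charges 2-5, one missed tryptic cleavage, and the sequon-forced
offsets excluded from motif scoring.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Union

from .masses import GlycanComposition
from .quant import RatioThresholds


@dataclass
class RunConfig:
    t_high: float = 4.0
    t_low: float = 1.0
    detection_limit: float = 0.0
    ms1_tolerance_ppm: float = 6.0
    ms2_tolerance_mmu: float = 20.0
    charges: tuple[int, ...] = (2, 3, 4, 5)
    max_missed_cleavages: int = 1
    glycan: str = "HexNAc5Hex3Fuc1"
    motif_k: int = 5
    motif_permutations: int = 1000
    motif_alpha: float = 0.05
    motif_excluded_offsets: tuple[int, ...] = (0, 2)
    seed: int = 1
    output_dir: str = "glycotrace_out"

    @property
    def thresholds(self) -> RatioThresholds:
        return RatioThresholds(t_high=self.t_high, t_low=self.t_low)

    @property
    def glycan_composition(self) -> GlycanComposition:
        return GlycanComposition.parse(self.glycan)

    @classmethod
    def from_toml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("charges", "motif_excluded_offsets"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
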