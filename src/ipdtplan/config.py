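"""Run configuration: one structured record mirrored by every CLI flag.

Defaults encode the planning conventions: 635 nm sources at 200 mW per cm of
diffuser, 131,072 photon packets per fiber, one hour of illumination, a
25 J/cm^2 therapeutic threshold with a 250 J/cm^2 high-dose display
threshold, and a 9 mm minimum spacing between diffusing parts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    labels_path: Optional[str] = None
    target_path: Optional[str] = None
    plan_path: Optional[str] = None
    profiles_path: Optional[str] = None
    tissue_table_path: Optional[str] = None
    out_dir: str = "."

    wavelength_nm: float = 635.0
    linear_power_mw_per_cm: float = 200.0
    n_packets: int = 131072
    treatment_time_s: float = 3600.0
    threshold_j_per_cm2: float = 25.0
    high_dose_threshold_j_per_cm2: float = 250.0
    min_spacing_mm: float = 9.0
    crossing_clearance_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")
        if self.linear_power_mw_per_cm < 0:
            raise ValueError("linear power must be non-negative")
        if self.treatment_time_s < 0:
            raise ValueError("treatment time must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Short digest embedded in outputs so runs are re-derivable."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
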