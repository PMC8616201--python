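"""Fluence dosimetry: treated volume and coverage index.

Per-fiber fluence-rate maps (mW/cm^2) are summed voxelwise, multiplied by the
illumination time to obtain fluence (J/cm^2), and thresholded at the minimal
target fluence of 25 J/cm^2 to define the effective treated volume.  The
coverage index is the percentage of the contoured target volume contained in
the treated volume.  A second, higher display threshold (250 J/cm^2 by
default) marks the high-dose region immediately around each diffuser.

Both thresholds use a strict "higher than" comparison by default
(configurable to >= for sensitivity checks).

An optional photodynamic weighting multiplies the fluence by a per-tissue
relative photosensitizer (PpIX) factor before thresholding; it is OFF by
default because the treated volume is defined on fluence alone, but is
exposed because tumor-to-healthy PpIX ratios of up to 100:1 make the
biological dose strongly tissue-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .grid import VoxelGrid
from .tissue_optics import TissueLabel
from .units import MW_S_PER_J

#: Minimal target fluence defining the effective treated volume, J/cm^2.
TREATMENT_THRESHOLD_J_PER_CM2 = 25.0

#: Display threshold for the high-dose region around each diffuser, J/cm^2.
HIGH_DOSE_THRESHOLD_J_PER_CM2 = 250.0

#: Default illumination time, s (one hour of continuous illumination).
DEFAULT_TREATMENT_TIME_S = 3600.0

#: Default relative PpIX concentration per tissue (100:1 tumor:healthy).
DEFAULT_PPIX_FACTORS: Dict[int, float] = {
    int(TissueLabel.BACKGROUND): 0.0,
    int(TissueLabel.CSF): 0.01,
    int(TissueLabel.GREY_MATTER): 0.01,
    int(TissueLabel.WHITE_MATTER): 0.01,
    int(TissueLabel.NECROTIC): 1.0,
    int(TissueLabel.NON_ENHANCING): 1.0,
    int(TissueLabel.ENHANCING): 1.0,
    int(TissueLabel.OEDEMA): 0.01,
}


@dataclass
class DoseSummary:
    """Dosimetry quantities reported on the plan."""

    treated_volume_cm3: float
    coverage_index_pct: Optional[float]
    treatment_time_s: float
    threshold_j_per_cm2: float
    high_dose_volume_cm3: float
    high_dose_threshold_j_per_cm2: float = HIGH_DOSE_THRESHOLD_J_PER_CM2

    def __post_init__(self):
        if self.treated_volume_cm3 < 0 or self.high_dose_volume_cm3 < 0:
            raise ValueError("volumes must be non-negative")
        if self.coverage_index_pct is not None and not 0 <= self.coverage_index_pct <= 100:
            raise ValueError("coverage index must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "treated_volume_cm3": self.treated_volume_cm3,
            "coverage_index_pct": self.coverage_index_pct,
            "treatment_time_s": self.treatment_time_s,
            "threshold_j_per_cm2": self.threshold_j_per_cm2,
            "high_dose_volume_cm3": self.high_dose_volume_cm3,
            "high_dose_threshold_j_per_cm2": self.high_dose_threshold_j_per_cm2,
        }


def sum_fluence_rates(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Voxelwise sum of per-fiber fluence-rate maps (all on the same grid)."""
    if len(maps) == 0:
        raise ValueError("at least one fluence-rate map is required")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError(f"fluence-rate maps on different grids: {m.shape} vs {shape}")
    out = np.zeros(shape, dtype=np.float64)
    for m in maps:
        out += m
    return out


def compute_fluence(rate_map: np.ndarray, time_s: float) -> np.ndarray:
    """Fluence (J/cm^2) = fluence rate (mW/cm^2) x time (s) / 1000."""
    if time_s < 0:
        raise ValueError(f"treatment time must be non-negative, got {time_s}")
    return np.asarray(rate_map, dtype=float) * (time_s / MW_S_PER_J)


def effective_treated_volume(
    fluence: np.ndarray,
    grid: VoxelGrid,
    threshold_j_per_cm2: float = TREATMENT_THRESHOLD_J_PER_CM2,
    strict: bool = True,
) -> Tuple[np.ndarray, float]:
    """Treated mask (fluence strictly above threshold) and its volume in cm^3."""
    if threshold_j_per_cm2 <= 0:
        raise ValueError("threshold must be positive")
    if fluence.shape != grid.shape:
        raise ValueError(f"fluence shape {fluence.shape} != grid shape {grid.shape}")
    mask = fluence > threshold_j_per_cm2 if strict else fluence >= threshold_j_per_cm2
    volume_cm3 = float(mask.sum()) * grid.voxel_volume_mm3 / 1000.0
    return mask, volume_cm3


def coverage_index(treated_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Percentage of the contoured target covered by the treated volume."""
    treated_mask = np.asarray(treated_mask, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    if treated_mask.shape != target_mask.shape:
        raise ValueError("treated and target masks must share the grid")
    n_target = int(target_mask.sum())
    if n_target == 0:
        raise ValueError("target mask is empty")
    return 100.0 * int((treated_mask & target_mask).sum()) / n_target


def high_dose_region(
    fluence: np.ndarray,
    display_threshold_j_per_cm2: float = HIGH_DOSE_THRESHOLD_J_PER_CM2,
    strict: bool = True,
) -> np.ndarray:
    """Mask of the high-dose region (for display and the plan report)."""
    if display_threshold_j_per_cm2 <= 0:
        raise ValueError("display threshold must be positive")
    return (fluence > display_threshold_j_per_cm2 if strict
            else fluence >= display_threshold_j_per_cm2)


def apply_ppix_weighting(
    fluence: np.ndarray,
    labels: np.ndarray,
    factors: Optional[Mapping[int, float]] = None,
) -> np.ndarray:
    """Multiply fluence by a per-tissue relative photosensitizer factor."""
    if factors is None:
        factors = DEFAULT_PPIX_FACTORS
    weight = np.zeros(int(labels.max()) + 1)
    for lab, f in factors.items():
        if lab <= labels.max():
            weight[lab] = f
    return fluence * weight[labels]


def summarize_dose(
    fluence: np.ndarray,
    grid: VoxelGrid,
    target_mask: Optional[np.ndarray] = None,
    treatment_time_s: float = DEFAULT_TREATMENT_TIME_S,
    threshold_j_per_cm2: float = TREATMENT_THRESHOLD_J_PER_CM2,
    high_dose_threshold_j_per_cm2: float = HIGH_DOSE_THRESHOLD_J_PER_CM2,
    strict: bool = True,
) -> Tuple[DoseSummary, np.ndarray, np.ndarray]:
    """Full dosimetry summary: (summary, treated mask, high-dose mask)."""
    treated_mask, treated_cm3 = effective_treated_volume(
        fluence, grid, threshold_j_per_cm2, strict=strict
    )
    hd_mask = high_dose_region(fluence, high_dose_threshold_j_per_cm2, strict=strict)
    hd_cm3 = float(hd_mask.sum()) * grid.voxel_volume_mm3 / 1000.0
    cov = coverage_index(treated_mask, target_mask) if target_mask is not None else None
    summary = DoseSummary(
        treated_volume_cm3=treated_cm3,
        coverage_index_pct=cov,
        treatment_time_s=treatment_time_s,
        threshold_j_per_cm2=threshold_j_per_cm2,
        high_dose_volume_cm3=hd_cm3,
        high_dose_threshold_j_per_cm2=high_dose_threshold_j_per_cm2,
    )
    return summary, treated_mask, hd_mask
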