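"""Synthetic segmented-brain phantoms and emission-profile fixtures.

Real inputs to the planning pipeline are a seven-class brain segmentation and
a manually contoured target; the generators here emulate both so that every
stage is testable without patient data.  The default phantom places a
concentric tumor (necrotic core, enhancing rim, non-enhancing region,
perilesional oedema shell) inside a white-matter brain sphere with a
grey-matter cortical shell and ventricle-like CSF inclusions, on a 1 mm
isotropic grid matching the clinical MRI resolution (a smaller fast profile
exists for quick runs).  Geometry is purely deterministic; the seed only
matters for generators that add noise (emission profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import PhantomSpecError
from .fiber_source import EmissionProfile, SuperGaussianParams
from .grid import VoxelGrid
from .tissue_optics import TissueLabel


@dataclass
class PhantomSpec:
    """Geometry of a synthetic segmented brain.

    All positions/radii in mm, world coordinates (voxel (0,0,0) centered at
    the origin).  Tumor radii must be strictly nested:
    necrotic < enhancing < non-enhancing < oedema.
    """

    shape: Tuple[int, int, int] = (120, 120, 120)
    voxel_size_mm: float = 1.0
    brain_radius_mm: Optional[float] = None   # default: 0.45 x smallest extent
    grey_thickness_mm: float = 3.0
    tumor_center_mm: Optional[Tuple[float, float, float]] = None
    necrotic_radius_mm: float = 6.0
    enhancing_radius_mm: float = 10.0
    non_enhancing_radius_mm: float = 14.0
    oedema_radius_mm: float = 20.0
    csf_inclusions: Optional[Sequence[Tuple[Tuple[float, float, float],
                                            Tuple[float, float, float]]]] = None
    include_oedema_in_target: bool = False
    seed: int = 0

    def __post_init__(self):
        extent = np.asarray(self.shape) * self.voxel_size_mm
        if self.brain_radius_mm is None:
            self.brain_radius_mm = 0.45 * float(extent.min())
        if self.tumor_center_mm is None:
            c = (extent - self.voxel_size_mm) / 2.0
            self.tumor_center_mm = tuple(c + np.array([0.25, 0.1, 0.0]) * self.brain_radius_mm)
        if self.csf_inclusions is None:
            c = (extent - self.voxel_size_mm) / 2.0
            r = self.brain_radius_mm
            semi = (0.08 * r, 0.3 * r, 0.16 * r)
            self.csf_inclusions = [
                (tuple(c + np.array([-0.22 * r, 0.0, 0.15 * r])), semi),
                (tuple(c + np.array([+0.22 * r, 0.0, 0.15 * r])), semi),
            ]
        radii = (self.necrotic_radius_mm, self.enhancing_radius_mm,
                 self.non_enhancing_radius_mm, self.oedema_radius_mm)
        if not all(a < b for a, b in zip(radii, radii[1:])):
            raise PhantomSpecError(f"tumor radii must be strictly nested, got {radii}")
        center = np.asarray(self.tumor_center_mm)
        lo = center - self.oedema_radius_mm
        hi = center + self.oedema_radius_mm
        if np.any(lo < 0) or np.any(hi > extent):
            raise PhantomSpecError("tumor compartments exceed the grid extent")

    @classmethod
    def fast(cls, **overrides) -> "PhantomSpec":
        """A 60^3 profile with proportionally smaller tumor, for quick runs."""
        defaults = dict(
            shape=(60, 60, 60), necrotic_radius_mm=3.0, enhancing_radius_mm=5.0,
            non_enhancing_radius_mm=7.0, oedema_radius_mm=10.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _world_coords(shape, voxel_size):
    axes = [np.arange(n) * voxel_size for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelGrid, np.ndarray]:
    """Build the labelled grid and the contoured target mask.

    The target is the union of the solid tumor compartments (necrotic +
    enhancing + non-enhancing); set ``include_oedema_in_target`` to extend it
    into the perilesional oedema.
    """
    X, Y, Z = _world_coords(spec.shape, spec.voxel_size_mm)
    extent = np.asarray(spec.shape) * spec.voxel_size_mm
    brain_center = (extent - spec.voxel_size_mm) / 2.0

    labels = np.zeros(spec.shape, dtype=np.int16)
    r_brain = np.sqrt((X - brain_center[0]) ** 2 + (Y - brain_center[1]) ** 2
                      + (Z - brain_center[2]) ** 2)
    brain = r_brain <= spec.brain_radius_mm
    labels[brain] = TissueLabel.WHITE_MATTER
    cortex = brain & (r_brain > spec.brain_radius_mm - spec.grey_thickness_mm)
    labels[cortex] = TissueLabel.GREY_MATTER

    for center, semi in spec.csf_inclusions:
        e = (((X - center[0]) / semi[0]) ** 2 + ((Y - center[1]) / semi[1]) ** 2
             + ((Z - center[2]) / semi[2]) ** 2)
        labels[(e <= 1.0) & brain] = TissueLabel.CSF

    tc = spec.tumor_center_mm
    r_tumor = np.sqrt((X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2)
    labels[r_tumor <= spec.oedema_radius_mm] = TissueLabel.OEDEMA
    labels[r_tumor <= spec.non_enhancing_radius_mm] = TissueLabel.NON_ENHANCING
    labels[r_tumor <= spec.enhancing_radius_mm] = TissueLabel.ENHANCING
    labels[r_tumor <= spec.necrotic_radius_mm] = TissueLabel.NECROTIC

    target = np.isin(labels, (TissueLabel.NECROTIC, TissueLabel.ENHANCING,
                              TissueLabel.NON_ENHANCING))
    if spec.include_oedema_in_target:
        target |= labels == TissueLabel.OEDEMA

    grid = VoxelGrid.from_spacing(labels, spec.voxel_size_mm)
    return grid, target


def homogeneous_phantom(
    label: int = TissueLabel.WHITE_MATTER,
    shape: Tuple[int, int, int] = (80, 80, 80),
    voxel_size_mm: float = 1.0,
) -> VoxelGrid:
    """A uniform single-tissue grid (oracle configurations)."""
    labels = np.full(shape, int(label), dtype=np.int16)
    return VoxelGrid.from_spacing(labels, voxel_size_mm)


def generate_emission_profile(
    length_mm: float,
    center_mm: Optional[float] = None,
    width_mm: Optional[float] = None,
    order: float = 3.0,
    noise_sd: float = 0.0,
    n_samples: int = 101,
    seed: int = 0,
) -> EmissionProfile:
    """Synthetic diffuser emission profile: super-Gaussian + Gaussian noise.

    Stand-in for a measured bench profile; intensities are the normalized
    density evaluated at uniformly spaced axial positions, perturbed by
    additive Gaussian noise (sd relative to the peak) and clipped at zero.
    """
    if center_mm is None:
        center_mm = length_mm / 2.0
    if width_mm is None:
        width_mm = 0.4 * length_mm
    params = SuperGaussianParams(center_mm=center_mm, width_mm=width_mm,
                                 order=order, support_mm=length_mm)
    z = np.linspace(0.0, length_mm, n_samples)
    y = params.pdf(z)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * y.max(), size=y.shape)
        y = np.clip(y, 0.0, None)
    return EmissionProfile(positions_mm=z, intensities=y)


def uniform_fluence_fixture(grid: VoxelGrid, value_j_per_cm2: float,
                            region_mask: np.ndarray) -> np.ndarray:
    """Fluence map equal to ``value`` inside the region mask, 0 outside."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != grid.shape:
        raise ValueError("region mask must match the grid shape")
    out = np.zeros(grid.shape, dtype=float)
    out[region_mask] = value_j_per_cm2
    return out
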