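"""Monte Carlo photon transport on the labelled voxel grid.

One call simulates one light source (a positioned cylindrical diffuser or an
isotropic point source, the latter mainly for validation against diffusion
theory) and returns per-voxel fluence-rate maps in mW/cm^2 scaled to the
source's total power.

Two estimators of the same fluence are produced.  The default, the
track-length tally ``sum(weight x chord) / (voxel volume x n_packets) x P``,
remains well-behaved in weakly absorbing tissue such as CSF; the absorption
tally ``deposited / (mu_a x voxel volume x n_packets) x P`` is retained as an
internal cross-check (the two agree within Monte Carlo error on homogeneous
phantoms).

Reproducibility contract: identical (grid, source, n_packets, seed) produce
bit-identical tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from ._kernel import run_packets
from .errors import GeometryError, UnknownTissueError
from .fiber_source import LineSource, sample_isotropic_directions
from .grid import VoxelGrid, traverse_voxels  # noqa: F401  (re-exported)
from .tissue_optics import TissueTable
from .units import MM2_PER_CM2

#: Default number of photon packets per fiber (2^17, the TPS trade-off
#: between run time and simulation quality).
DEFAULT_N_PACKETS = 131072

#: Russian-roulette defaults (weight threshold and survival probability).
DEFAULT_ROULETTE_THRESHOLD = 1e-4
DEFAULT_ROULETTE_SURVIVAL = 0.1

_MAX_STEPS_PER_PACKET = 50_000_000


def henyey_greenstein_cosine(g: float, u) -> np.ndarray:
    """Sample the Henyey-Greenstein scattering cosine from uniform variates.

    For ``g != 0`` returns ``(1 + g^2 - ((1 - g^2) / (1 - g + 2 g u))^2) / (2 g)``;
    for ``g == 0`` the isotropic limit ``2 u - 1``.  Results lie in [-1, 1].
    """
    if not -1.0 <= g <= 1.0:
        raise ValueError(f"anisotropy g must lie in [-1, 1], got {g}")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(out, -1.0, 1.0)


@dataclass
class TransportResult:
    """Tallies of one transport run.

    ``fluence_rate`` (track-length estimator) and ``fluence_rate_absorption``
    are in mW/cm^2, scaled to the source's total power; ``deposited_weight``
    and ``escaped_weight`` are packet-weight units (launched weight equals
    ``n_launched``).
    """

    fluence_rate: np.ndarray
    fluence_rate_absorption: np.ndarray
    deposited_weight: np.ndarray
    escaped_weight: float
    n_launched: int
    seed: int
    total_power_mw: float

    @property
    def conservation_defect(self) -> float:
        """Relative defect of launched = deposited + escaped (0 with roulette off)."""
        total = float(self.deposited_weight.sum()) + self.escaped_weight
        return abs(total - self.n_launched) / self.n_launched

    def summary(self) -> dict:
        return {
            "n_launched": self.n_launched,
            "seed": self.seed,
            "total_power_mw": self.total_power_mw,
            "deposited_weight": float(self.deposited_weight.sum()),
            "escaped_weight": self.escaped_weight,
            "conservation_defect": self.conservation_defect,
        }


def _prepare_properties(grid: VoxelGrid, table: TissueTable):
    present = np.unique(grid.labels)
    for lab in present:
        if int(lab) not in table:
            raise UnknownTissueError(int(lab))
    return table.to_arrays()


def _simulate(
    grid: VoxelGrid,
    table: TissueTable,
    positions_world: np.ndarray,
    directions: np.ndarray,
    total_power_mw: float,
    seed: int,
    kernel_seed: np.uint64,
    roulette_threshold: float,
    roulette_survival: float,
    use_roulette: bool,
) -> TransportResult:
    grid.require_axis_aligned()
    mu_a, mu_s, g_fac = _prepare_properties(grid, table)
    vs = grid.voxel_size_mm
    corner = grid.corner_origin_mm
    pos = np.ascontiguousarray(positions_world - corner, dtype=float)
    if np.any(pos < 0) or np.any(pos >= np.asarray(grid.shape) * vs):
        raise GeometryError("one or more launch positions fall outside the grid")

    n = pos.shape[0]
    track = np.zeros(grid.shape, dtype=np.float64)
    absorbed = np.zeros(grid.shape, dtype=np.float64)
    labels = grid.labels.astype(np.int16)
    escaped = run_packets(
        labels,
        np.ascontiguousarray(mu_a), np.ascontiguousarray(mu_s),
        np.ascontiguousarray(g_fac),
        float(vs[0]), float(vs[1]), float(vs[2]),
        np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
        np.ascontiguousarray(pos[:, 2]),
        np.ascontiguousarray(directions[:, 0], dtype=float),
        np.ascontiguousarray(directions[:, 1], dtype=float),
        np.ascontiguousarray(directions[:, 2], dtype=float),
        np.uint64(kernel_seed),
        float(roulette_threshold), float(roulette_survival), bool(use_roulette),
        _MAX_STEPS_PER_PACKET,
        track, absorbed,
    )

    v_mm3 = grid.voxel_volume_mm3
    scale = total_power_mw * MM2_PER_CM2 / (v_mm3 * n)
    fluence_rate = track * scale

    mu_a_map = mu_a[labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        fra = np.where(mu_a_map > 0, absorbed / np.where(mu_a_map > 0, mu_a_map, 1.0), 0.0)
    fluence_rate_absorption = fra * scale

    return TransportResult(
        fluence_rate=fluence_rate,
        fluence_rate_absorption=fluence_rate_absorption,
        deposited_weight=absorbed,
        escaped_weight=float(escaped),
        n_launched=n,
        seed=seed,
        total_power_mw=total_power_mw,
    )


def _seed_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    kernel_seed = np.uint64(ss.generate_state(1, dtype=np.uint64)[0])
    return rng, kernel_seed


def run_transport(
    grid: VoxelGrid,
    table: TissueTable,
    source: LineSource,
    n_packets: int = DEFAULT_N_PACKETS,
    seed: int = 0,
    roulette_threshold: float = DEFAULT_ROULETTE_THRESHOLD,
    roulette_survival: float = DEFAULT_ROULETTE_SURVIVAL,
    use_roulette: bool = True,
) -> TransportResult:
    """Simulate one positioned diffuser on the grid.

    Launch positions are drawn from the source's fitted axial emission density
    and mapped onto the diffusing segment; launch directions are isotropic;
    every packet starts with unit weight.  The returned fluence-rate maps are
    scaled to the source's total power (linear power x length).
    """
    if n_packets < 1:
        raise ValueError("n_packets must be >= 1")
    if not grid.contains_segment(source.proximal_mm, source.distal_mm):
        raise GeometryError("the diffusing segment must lie inside the grid")
    rng, kernel_seed = _seed_streams(seed)
    positions = source.launch_positions(n_packets, rng)
    directions = sample_isotropic_directions(n_packets, rng)
    return _simulate(
        grid, table, positions, directions, source.total_power_mw,
        seed, kernel_seed, roulette_threshold, roulette_survival, use_roulette,
    )


def run_point_source(
    grid: VoxelGrid,
    table: TissueTable,
    center_mm,
    power_mw: float = 1.0,
    n_packets: int = DEFAULT_N_PACKETS,
    seed: int = 0,
    roulette_threshold: float = DEFAULT_ROULETTE_THRESHOLD,
    roulette_survival: float = DEFAULT_ROULETTE_SURVIVAL,
    use_roulette: bool = True,
) -> TransportResult:
    """Simulate an isotropic point source (validation oracle configuration)."""
    center = np.asarray(center_mm, dtype=float)
    if not grid.contains_world(center):
        raise GeometryError(f"point source {tuple(center)} mm is outside the grid")
    rng, kernel_seed = _seed_streams(seed)
    positions = np.tile(center, (n_packets, 1))
    directions = sample_isotropic_directions(n_packets, rng)
    return _simulate(
        grid, table, positions, directions, power_mw,
        seed, kernel_seed, roulette_threshold, roulette_survival, use_roulette,
    )
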