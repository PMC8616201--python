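"""Stereotactic fiber-plan geometry: trajectories, spacing rules and reports.

Fiber trajectories are defined by an entry point and a target point in
stereotactic millimetre coordinates (X medial-lateral, Y anterior-posterior,
Z cranial-caudal).  The diffusing part of the fiber ends at the target point
and extends back toward the entry point by the diffuser length.

Plan validation enforces the clinical placement rules: diffusing parts of any
two fibers must be at least ``min_spacing`` (default 9 mm) apart to avoid
thermal hot spots, insertion paths must not cross, diffuser lengths must come
from the manufacturable set (2, 2.5, 3, 4, 5 cm), and every fiber must lie
inside the simulation grid.  Violations are reported as alerts rather than
exceptions so that the user can adjust the plan; report export and simulation
refuse to proceed while alerts remain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import GeometryError, PlanNotValidatedError

#: Manufacturable diffuser lengths, mm (2, 2.5, 3, 4 and 5 cm).
ALLOWED_DIFFUSER_LENGTHS_MM = (20.0, 25.0, 30.0, 40.0, 50.0)

#: Default minimum spacing between diffusing parts, mm (43 degC thermal rule).
DEFAULT_MIN_SPACING_MM = 9.0

#: Default clearance below which two insertion paths count as crossing, mm.
DEFAULT_CROSSING_CLEARANCE_MM = 1.0


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"expected a 3-vector in mm, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class FiberTrajectory:
    """One fiber: entry and target points (mm) plus the diffuser length (mm).

    The entry point is where the fiber pierces the skull; the target point is
    the distal end of the inserted fiber.  ``entry != target`` and the track
    must be at least as long as the diffusing part.
    """

    entry: Tuple[float, float, float]
    target: Tuple[float, float, float]
    diffuser_length_mm: float

    def __post_init__(self):
        e = _as_point(self.entry)
        t = _as_point(self.target)
        object.__setattr__(self, "entry", tuple(e))
        object.__setattr__(self, "target", tuple(t))
        if self.diffuser_length_mm <= 0:
            raise GeometryError(
                f"diffuser length must be positive, got {self.diffuser_length_mm}"
            )
        track = float(np.linalg.norm(t - e))
        if track == 0.0:
            raise GeometryError("entry and target points coincide")
        if track < self.diffuser_length_mm:
            raise GeometryError(
                f"insertion track ({track:.3f} mm) is shorter than the "
                f"diffusing part ({self.diffuser_length_mm} mm)"
            )

    @property
    def track_length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.target, self.entry)))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry toward target."""
        d = np.subtract(self.target, self.entry)
        return d / np.linalg.norm(d)

    def has_allowed_length(self, tol: float = 1e-9) -> bool:
        return any(
            abs(self.diffuser_length_mm - L) <= tol for L in ALLOWED_DIFFUSER_LENGTHS_MM
        )


def diffuser_segment(traj: FiberTrajectory) -> Tuple[np.ndarray, np.ndarray]:
    """Endpoints (proximal, distal) of the diffusing part, distal at the target."""
    target = np.asarray(traj.target, dtype=float)
    proximal = target - traj.direction * traj.diffuser_length_mm
    return proximal, target


def segment_min_distance(a0, a1, b0, b1) -> float:
    """Minimum Euclidean distance between two closed 3D segments, mm.

    Standard clamped closest-point computation between segments
    ``a0 + s (a1 - a0)`` and ``b0 + t (b1 - b0)``, s, t in [0, 1].
    """
    a0 = _as_point(a0); a1 = _as_point(a1)
    b0 = _as_point(b0); b1 = _as_point(b1)
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = float(d1 @ d1)
    e = float(d2 @ d2)
    f = float(d2 @ r)
    eps = 1e-15
    if a <= eps and e <= eps:
        return float(np.linalg.norm(r))
    if a <= eps:
        s = 0.0
        t = np.clip(f / e, 0.0, 1.0)
    else:
        c = float(d1 @ r)
        if e <= eps:
            t = 0.0
            s = np.clip(-c / a, 0.0, 1.0)
        else:
            b = float(d1 @ d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > eps else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t = 1.0
                s = np.clip((b - c) / a, 0.0, 1.0)
    closest_a = a0 + s * d1
    closest_b = b0 + t * d2
    return float(np.linalg.norm(closest_a - closest_b))


@dataclass(frozen=True)
class Alert:
    """One validation finding; carries the offending measurement."""

    kind: str  # spacing-violation | trajectory-crossing | invalid-length | out-of-grid
    fibers: Tuple[int, ...]
    value: float
    message: str

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "fibers": list(self.fibers),
            "value": self.value,
            "message": self.message,
        }


@dataclass
class Plan:
    """An ordered list of fiber trajectories plus the simulation settings."""

    fibers: List[FiberTrajectory]
    treatment_time_s: float = 3600.0
    n_packets: int = 131072
    seed: int = 0

    def __post_init__(self):
        if not self.fibers:
            raise ValueError("a plan must contain at least one fiber")
        if self.treatment_time_s < 0:
            raise ValueError("treatment time must be non-negative")
        if self.n_packets < 1:
            raise ValueError("n_packets must be >= 1")


def validate_plan(
    plan: Plan,
    grid=None,
    min_spacing_mm: float = DEFAULT_MIN_SPACING_MM,
    crossing_clearance_mm: float = DEFAULT_CROSSING_CLEARANCE_MM,
) -> List[Alert]:
    """Check a plan against the placement rules; return alerts (empty == valid).

    Diffuser spacing uses the closed diffusing segments: a pairwise distance
    strictly below ``min_spacing_mm`` raises a spacing-violation (exactly
    ``min_spacing_mm`` passes, "at least 9 mm apart").  Crossing uses the full
    entry-to-target insertion paths against ``crossing_clearance_mm``.  When a
    ``grid`` is supplied, each fiber's entry, target and diffusing part must
    lie inside it.
    """
    alerts: List[Alert] = []
    segs = [diffuser_segment(t) for t in plan.fibers]

    for i, traj in enumerate(plan.fibers):
        if not traj.has_allowed_length():
            alerts.append(Alert(
                kind="invalid-length",
                fibers=(i,),
                value=traj.diffuser_length_mm,
                message=(
                    f"fiber {i}: diffuser length {traj.diffuser_length_mm} mm is not in "
                    f"the allowed set {sorted(ALLOWED_DIFFUSER_LENGTHS_MM)} mm"
                ),
            ))
        if grid is not None:
            points = [np.asarray(traj.entry), np.asarray(traj.target), segs[i][0]]
            for p in points:
                if not grid.contains_world(p):
                    alerts.append(Alert(
                        kind="out-of-grid",
                        fibers=(i,),
                        value=float(np.linalg.norm(p)),
                        message=f"fiber {i}: point {tuple(np.round(p, 3))} mm lies outside the grid",
                    ))
                    break

    n = len(plan.fibers)
    for i in range(n):
        for j in range(i + 1, n):
            d_diff = segment_min_distance(*segs[i], *segs[j])
            if d_diff < min_spacing_mm:
                alerts.append(Alert(
                    kind="spacing-violation",
                    fibers=(i, j),
                    value=d_diff,
                    message=(
                        f"fibers {i} and {j}: diffusing parts are {d_diff:.3f} mm apart "
                        f"(minimum {min_spacing_mm} mm)"
                    ),
                ))
            d_track = segment_min_distance(
                np.asarray(plan.fibers[i].entry), np.asarray(plan.fibers[i].target),
                np.asarray(plan.fibers[j].entry), np.asarray(plan.fibers[j].target),
            )
            if d_track < crossing_clearance_mm:
                alerts.append(Alert(
                    kind="trajectory-crossing",
                    fibers=(i, j),
                    value=d_track,
                    message=(
                        f"fibers {i} and {j}: insertion paths approach to {d_track:.3f} mm "
                        f"(clearance {crossing_clearance_mm} mm)"
                    ),
                ))
    return alerts


# -------------------------------------------------------------- coordinates


def world_to_voxel(point, grid) -> Tuple[int, int, int]:
    """Nearest voxel index (0-based, voxel-center convention) of a world point.

    Raises :class:`~ipdtplan.errors.OutOfGridError` for points outside the
    grid bounds.
    """
    return grid.world_to_voxel(point)


def voxel_to_world(index, grid) -> np.ndarray:
    """World coordinates (mm) of a voxel center."""
    return grid.voxel_to_world(index)


# ---------------------------------------------------------------- plan I/O


def plan_to_dict(plan: Plan) -> dict:
    return {
        "fibers": [
            {
                "entry_mm": list(t.entry),
                "target_mm": list(t.target),
                "diffuser_length_mm": t.diffuser_length_mm,
            }
            for t in plan.fibers
        ],
        "treatment_time_s": plan.treatment_time_s,
        "n_packets": plan.n_packets,
        "seed": plan.seed,
    }


def plan_from_dict(d: dict) -> Plan:
    fibers = [
        FiberTrajectory(
            entry=tuple(f["entry_mm"]),
            target=tuple(f["target_mm"]),
            diffuser_length_mm=float(f["diffuser_length_mm"]),
        )
        for f in d["fibers"]
    ]
    return Plan(
        fibers=fibers,
        treatment_time_s=float(d.get("treatment_time_s", 3600.0)),
        n_packets=int(d.get("n_packets", 131072)),
        seed=int(d.get("seed", 0)),
    )


def write_plan(plan: Plan, path) -> None:
    Path(path).write_text(json.dumps(plan_to_dict(plan), indent=2) + "\n")


def read_plan(path) -> Plan:
    return plan_from_dict(json.loads(Path(path).read_text()))


# ------------------------------------------------------------------ report


def export_plan_report(
    plan: Plan,
    alerts: Sequence[Alert],
    dose_summary=None,
    sources: Optional[Sequence] = None,
    path=None,
    extra: Optional[dict] = None,
) -> dict:
    """Assemble (and optionally write) the final plan report.

    Refuses to export while validation alerts remain, mirroring the clinical
    workflow gate.  The report carries, per fiber, the stereotactic entry and
    target coordinates, diffuser length and linear power, plus the dosimetry
    summary, seeds and software version; it round-trips losslessly through
    JSON.
    """
    from . import __version__

    if alerts:
        raise PlanNotValidatedError(alerts)

    fibers = []
    for i, traj in enumerate(plan.fibers):
        rec = {
            "index": i,
            "entry_mm": {"x": traj.entry[0], "y": traj.entry[1], "z": traj.entry[2]},
            "target_mm": {"x": traj.target[0], "y": traj.target[1], "z": traj.target[2]},
            "diffuser_length_mm": traj.diffuser_length_mm,
        }
        if sources is not None and i < len(sources):
            src = sources[i]
            rec["linear_power_mw_per_cm"] = src.linear_power_mw_per_cm
            rec["total_power_mw"] = src.total_power_mw
            rec["emission_pdf"] = {
                "center_mm": src.params.center_mm,
                "width_mm": src.params.width_mm,
                "order": src.params.order,
                "support_mm": src.params.support_mm,
            }
        fibers.append(rec)

    report = {
        "software": {"name": "ipdtplan", "version": __version__},
        "plan": {
            "treatment_time_s": plan.treatment_time_s,
            "n_packets_per_fiber": plan.n_packets,
            "seed": plan.seed,
        },
        "fibers": fibers,
        "alerts": [],
    }
    if dose_summary is not None:
        report["dosimetry"] = dose_summary.to_dict()
    if extra:
        report.update(extra)
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report
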