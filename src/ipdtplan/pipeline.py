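"""End-to-end orchestration: validate, simulate per fiber, summarize, report.

The workflow is gate-ordered like the clinical planning interface: a plan
must validate cleanly (no spacing, crossing, length or containment alerts)
before any simulation runs, and the report can only be exported for a
validated plan.

Per-fiber transport runs are seeded independently and deterministically from
the plan seed, so an N-fiber simulation is exactly the superposition of the N
single-fiber simulations run with the matching per-fiber seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import dosimetry, geometry
from .dosimetry import DoseSummary
from .errors import PlanNotValidatedError
from .fiber_source import LineSource, SuperGaussianParams, build_line_source
from .geometry import Alert, Plan
from .grid import VoxelGrid
from .tissue_optics import TissueTable, default_tissue_table
from .transport import TransportResult, run_transport


def fiber_seed(plan_seed: int, fiber_index: int) -> int:
    """Deterministic per-fiber transport seed derived from the plan seed."""
    ss = np.random.SeedSequence(entropy=plan_seed, spawn_key=(fiber_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class PlanResult:
    """Everything the simulation stage produces for one plan."""

    per_fiber: List[TransportResult]
    sources: List[LineSource]
    total_fluence_rate: np.ndarray  # mW/cm^2
    fluence: np.ndarray             # J/cm^2
    summary: DoseSummary
    treated_mask: np.ndarray
    high_dose_mask: np.ndarray
    report: dict


def simulate_plan(
    plan: Plan,
    grid: VoxelGrid,
    table: Optional[TissueTable] = None,
    target_mask: Optional[np.ndarray] = None,
    emission_params: Optional[Sequence[Optional[SuperGaussianParams]]] = None,
    linear_power_mw_per_cm: float = 200.0,
    threshold_j_per_cm2: float = dosimetry.TREATMENT_THRESHOLD_J_PER_CM2,
    high_dose_threshold_j_per_cm2: float = dosimetry.HIGH_DOSE_THRESHOLD_J_PER_CM2,
    min_spacing_mm: float = geometry.DEFAULT_MIN_SPACING_MM,
    crossing_clearance_mm: float = geometry.DEFAULT_CROSSING_CLEARANCE_MM,
    use_roulette: bool = True,
    validate: bool = True,
) -> PlanResult:
    """Run the full dosimetry pipeline for a validated plan.

    Raises :class:`~ipdtplan.errors.PlanNotValidatedError` when validation
    alerts remain (mirroring the planning interface, which blocks the user at
    that stage).
    """
    if table is None:
        table = default_tissue_table()
    alerts: List[Alert] = []
    if validate:
        alerts = geometry.validate_plan(
            plan, grid, min_spacing_mm=min_spacing_mm,
            crossing_clearance_mm=crossing_clearance_mm,
        )
        if alerts:
            raise PlanNotValidatedError(alerts)

    sources: List[LineSource] = []
    results: List[TransportResult] = []
    for i, traj in enumerate(plan.fibers):
        params = emission_params[i] if emission_params is not None else None
        src = build_line_source(traj, params=params,
                                linear_power_mw_per_cm=linear_power_mw_per_cm)
        sources.append(src)
        results.append(run_transport(
            grid, table, src, n_packets=plan.n_packets,
            seed=fiber_seed(plan.seed, i), use_roulette=use_roulette,
        ))

    total_rate = dosimetry.sum_fluence_rates([r.fluence_rate for r in results])
    fluence = dosimetry.compute_fluence(total_rate, plan.treatment_time_s)
    summary, treated_mask, hd_mask = dosimetry.summarize_dose(
        fluence, grid, target_mask=target_mask,
        treatment_time_s=plan.treatment_time_s,
        threshold_j_per_cm2=threshold_j_per_cm2,
        high_dose_threshold_j_per_cm2=high_dose_threshold_j_per_cm2,
    )

    report = geometry.export_plan_report(
        plan, alerts, dose_summary=summary, sources=sources,
        extra={
            "transport": [r.summary() for r in results],
            "per_fiber_seeds": [fiber_seed(plan.seed, i) for i in range(len(plan.fibers))],
        },
    )
    return PlanResult(
        per_fiber=results,
        sources=sources,
        total_fluence_rate=total_rate,
        fluence=fluence,
        summary=summary,
        treated_mask=treated_mask,
        high_dose_mask=hd_mask,
        report=report,
    )
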