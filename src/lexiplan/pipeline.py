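"""End-to-end two-phase auto-planning workflow.

Ties the modules together the way the clinical procedure does: build or
load a phantom, then for each phase place the isocentre at the phase
target's centre, compute the dose-influence matrix for 20 equi-angular
beams, resolve the packaged wishlist against the prescription, run the
prioritized optimizer, and finally sum the phases and evaluate the plan
against the clinical protocol.  The two phases are planned
independently, exactly as in the clinical workflow.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .dose import BeamSet, DoseInfluenceMatrix, PhysicsParams, compute_dij, make_beams
from .evaluation import MetricsReport, target_metrics
from .grid import StructureSet, VoxelGrid
from .optimizer import PlanResult, SolverSettings, solve_prioritized
from .phantom import PhantomSpec, default_grid, generate_phantom
from .wishlist import (PrescriptionContext, ResolvedProblem, Wishlist,
                       builtin_wishlist, resolve)

log = logging.getLogger(__name__)


@dataclass
class PhasePlan:
    """Everything produced while planning one phase."""

    phase: int
    beams: BeamSet
    dij: DoseInfluenceMatrix
    problem: ResolvedProblem
    result: PlanResult
    runtime_s: float


def plan_phase(
    structures: StructureSet,
    phase: int,
    context: PrescriptionContext = None,
    wishlist: Wishlist = None,
    n_beams: int = 20,
    beamlet_size_mm: float = 10.0,
    physics: PhysicsParams = None,
    settings: SolverSettings = None,
) -> PhasePlan:
    """Optimize one treatment phase on an existing structure set."""
    context = context or PrescriptionContext()
    wishlist = wishlist or builtin_wishlist(phase)
    physics = physics or PhysicsParams()
    settings = settings or SolverSettings()
    grid = structures.grid
    target = structures[wishlist.phase_target]

    t0 = time.perf_counter()
    beams = make_beams(n_beams, beamlet_size_mm=beamlet_size_mm,
                       target_mask=target, grid=grid)
    # only rays passing near the phase PTV carry useful fluence
    dij = compute_dij(grid, structures["external"], beams, physics,
                      prune_mask=target)
    problem = resolve(wishlist, context, structures)
    result = solve_prioritized(dij, problem, settings)
    runtime = time.perf_counter() - t0
    log.info("phase %d solved in %.1f s (%d beamlets)", phase, runtime, dij.n_beamlets)
    return PhasePlan(phase, beams, dij, problem, result, runtime)


@dataclass
class TwoPhasePlan:
    structures: StructureSet
    phase1: PhasePlan
    phase2: PhasePlan
    summed_dose: np.ndarray
    metrics: MetricsReport
    context: PrescriptionContext


def plan_two_phase(
    spec: PhantomSpec = None,
    structures: StructureSet = None,
    grid: VoxelGrid = None,
    context: PrescriptionContext = None,
    n_beams: int = 20,
    beamlet_size_mm: float = 10.0,
    physics: PhysicsParams = None,
    settings: SolverSettings = None,
) -> TwoPhasePlan:
    """Phantom (unless given) -> phase-1 plan -> phase-2 plan -> evaluation."""
    context = context or PrescriptionContext()
    if structures is None:
        spec = spec or PhantomSpec()
        structures = generate_phantom(spec, grid or default_grid(spec))
    plans: Dict[int, PhasePlan] = {}
    for phase in (1, 2):
        plans[phase] = plan_phase(structures, phase, context,
                                  n_beams=n_beams, beamlet_size_mm=beamlet_size_mm,
                                  physics=physics, settings=settings)
    summed = plans[1].result.dose + plans[2].result.dose
    metrics = target_metrics(
        summed, {1: plans[1].result.dose, 2: plans[2].result.dose},
        structures, context)
    return TwoPhasePlan(structures, plans[1], plans[2], summed, metrics, context)
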