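"""Tiny fluence problems with an exhaustive lexicographic oracle.

Shared by the optimizer unit tests and the acceptance suite.  Problems
are small enough (<= 3 beamlets, <= 6 voxels) that the prioritized
epsilon-constraint sweep can be reproduced by brute-force grid search
over the whole fluence box, which serves as the independent oracle.
"""

import numpy as np
from scipy import sparse

from lexiplan.costs import CostSpec
from lexiplan.dose import BeamSet, DoseInfluenceMatrix, PhysicsParams
from lexiplan.grid import VoxelGrid
from lexiplan.wishlist import (PrescriptionContext, ResolvedConstraint,
                               ResolvedObjective, ResolvedProblem)


def toy_dij(D: np.ndarray) -> DoseInfluenceMatrix:
    """Wrap a dense (voxels x beamlets) dose matrix as a DoseInfluenceMatrix."""
    D = np.asarray(D, float)
    m, n = D.shape
    grid = VoxelGrid((m, 1, 1), (1.0, 1.0, 1.0))
    table = np.zeros(n, dtype=[("beam", "i4"), ("row", "i4"), ("col", "i4"),
                               ("offset_a", "f8"), ("offset_b", "f8")])
    table["col"] = np.arange(n)
    return DoseInfluenceMatrix(
        matrix=sparse.csr_matrix(D),
        voxel_index=np.arange(m),
        beamlet_table=table,
        grid=grid,
        beams=BeamSet((0.0,), (0.0, 0.0, 0.0), 1, n),
        physics=PhysicsParams(calibration_gy=None),
    )


def toy_problem(constraints, objectives, m: int) -> ResolvedProblem:
    """Assemble a ResolvedProblem from shorthand tuples.

    constraints: (kind, voxel_idx, limit_gy)
    objectives:  (priority, CostSpec, voxel_idx, goal)
    """
    grid = VoxelGrid((m, 1, 1), (1.0, 1.0, 1.0))
    cons = []
    for i, (kind, vox, limit) in enumerate(constraints):
        vox = np.asarray(vox)
        cons.append(ResolvedConstraint(
            f"c{i} {kind} <= {limit:g}", f"s{i}", kind, float(limit), vox))
    objs = []
    for order, (priority, cost, vox, goal) in enumerate(objectives):
        objs.append(ResolvedObjective(
            priority, order, f"p{priority} {cost.kind}#{order}", f"o{order}",
            cost, float(goal), np.asarray(vox)))
    return ResolvedProblem("toy", 1, PrescriptionContext(), grid, cons, objs)


def random_instance(rng, n_beamlets=None, n_voxels=None):
    """A random feasible toy instance: 1 max hard constraint + 2-3 objectives."""
    n = n_beamlets or int(rng.integers(2, 4))
    m = n_voxels or int(rng.integers(3, 7))
    D = rng.uniform(0.2, 1.0, size=(m, n))
    D[rng.random(D.shape) < 0.25] = 0.0
    D[0, :] = np.maximum(D[0, :], 0.3)  # keep at least one coupled row

    def subset():
        k = int(rng.integers(1, m + 1))
        return np.sort(rng.choice(m, size=k, replace=False))

    constraints = [("MAX", np.arange(m), 12.0)]
    target = subset()
    objectives = [(1, CostSpec("LTCP", d_p=10.0, alpha=float(rng.uniform(0.5, 1.0))),
                   target, 0.6)]
    pool = [
        CostSpec("MEAN"),
        CostSpec("MAX"),
        CostSpec("EUD", k=float(rng.choice([2.0, 4.0]))),
    ]
    for prio in range(2, int(rng.integers(3, 5))):
        cost = pool[int(rng.integers(0, len(pool)))]
        goal = float(rng.uniform(1.0, 5.0))
        objectives.append((prio, cost, subset(), goal))
    return D, toy_problem(constraints, objectives, m)


def _stage_values(cost: CostSpec, doses: np.ndarray) -> np.ndarray:
    """Vectorized cost over a (points x voxels) dose block."""
    if cost.kind == "MEAN":
        return doses.mean(axis=1)
    if cost.kind == "MAX":
        return doses.max(axis=1)
    if cost.kind == "EUD":
        k = cost.k
        top = doses.max(axis=1, keepdims=True)
        top = np.where(top > 0, top, 1.0)
        return (top[:, 0]) * np.mean((doses / top) ** k, axis=1) ** (1.0 / k)
    e = np.exp(-cost.alpha * (doses - cost.d_p))
    return e.mean(axis=1)


def grid_search_lexicographic(D, problem, delta=1.03, points_2d=241, points_3d=81,
                              imposed_bounds=None):
    """Brute-force prioritized sweep over a fluence grid.

    Returns (stage_minima, dose_granularity): the per-stage attained
    minima under the same goal-capping / delta-relaxation bounding rule
    the solver uses, and a bound on the dose error introduced by the
    finite grid (used to set comparison tolerances).

    With ``imposed_bounds`` (one per stage, e.g. the bounds a solver
    recorded), the sweep filters with those instead of deriving its own,
    so each stage minimum is computed under the identical constraint
    set the solver faced — otherwise two correct runs can diverge
    whenever an earlier stage lands slightly lower and therefore
    carries a tighter bound forward.
    """
    D = np.asarray(D, float)
    m, n = D.shape
    hard_max = [(c.voxels, c.limit_gy) for c in problem.constraints if c.kind == "MAX"]
    xmax = np.full(n, 15.0)
    for vox, limit in hard_max:
        sub = D[vox]
        with np.errstate(divide="ignore"):
            caps = np.where(sub > 1e-12, limit / np.where(sub > 1e-12, sub, 1.0), np.inf)
        xmax = np.minimum(xmax, caps.min(axis=0))
    points = points_2d if n <= 2 else points_3d
    axes = [np.linspace(0.0, xmax[j], points) for j in range(n)]
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([g.ravel() for g in mesh], axis=1)
    dose = X @ D.T

    feasible = np.ones(X.shape[0], bool)
    for c in problem.constraints:
        block = dose[:, c.voxels]
        if c.kind == "MAX":
            feasible &= block.max(axis=1) <= c.limit_gy + 1e-9
        elif c.kind == "MEAN":
            feasible &= block.mean(axis=1) <= c.limit_gy + 1e-9
        else:  # MIN
            feasible &= block.min(axis=1) >= c.limit_gy - 1e-9
    assert feasible.any(), "oracle: no feasible grid point"

    step = np.array([a[1] - a[0] if a.size > 1 else 0.0 for a in axes])
    granularity = float((D @ step).max())

    minima = []
    ordered = sorted(problem.objectives, key=lambda o: (o.priority, o.order))
    for k, o in enumerate(ordered):
        vals = _stage_values(o.cost, dose[:, o.voxels])
        mn = float(vals[feasible].min())
        minima.append(mn)
        if imposed_bounds is not None:
            bound = imposed_bounds[k]
        else:
            bound = o.goal if mn <= o.goal else mn * delta
        narrowed = feasible & (vals <= bound * (1 + 1e-9) + 1e-12)
        if not narrowed.any():
            # an externally imposed bound sits below the grid floor:
            # keep the nearest grid points so the sweep can continue
            narrowed = feasible & (vals <= mn + granularity)
        feasible = narrowed
    return minima, granularity
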