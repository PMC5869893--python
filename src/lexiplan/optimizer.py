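"""The prioritized (lexicographic epsilon-constraint) fluence optimizer.

Given a dose-influence matrix and a resolved wishlist, the solver visits
the objectives in priority order.  Each stage minimizes one objective
subject to the hard constraints and to bounds imposed by all earlier
stages; afterwards the stage's objective is frozen: at its goal when the
goal was reached, else at the attained value times a small relaxation
factor ``delta``.  A second "tighten" pass then revisits every objective
and replaces its bound by the value actually attainable given all other
bounds, removing the relaxation slack, and a final stage picks the
minimum-norm fluence among the near-degenerate optima.  Because every
cost function is convex and the dose map is linear, each stage is a
convex program and the resulting bounds are globally valid, so the plan
is Pareto-consistent with the wishlist's priorities.

Each stage is solved with an augmented-Lagrangian outer loop whose inner
subproblems are minimized by a projected Newton-CG method: the
Lagrangian's Hessian-vector products only need sparse multiplies with
the dose-influence rows, which keeps second-order convergence at
first-order iteration cost.  Maximum-dose objectives use the epigraph
form (an auxiliary variable ``t`` with couplings ``d_i/s <= t``), and
per-voxel maximum-dose constraints over large structures are handled
through growing working sets of hot voxels that are re-verified against
the full voxel lists at every outer iteration, so the reduction is
exact at convergence.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

from .costs import CostSpec
from .dose import DoseInfluenceMatrix
from .errors import InfeasibleProblemError, SolverError
from .wishlist import ResolvedProblem

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverSettings:
    """Tunables of the prioritized solver.

    ``delta`` is the relaxation applied to an objective bound when the
    goal was missed (1.03 = 3%); the tighten pass removes most of this
    slack again.  A hard constraint with limit L is accepted when its
    value is within ``max(constraint_tol_gy, constraint_tol_rel * L)``.
    """

    delta: float = 1.03
    constraint_tol_gy: float = 0.05
    constraint_tol_rel: float = 1e-3
    ltcp_log_tol: float = 1e-3
    tighten_pass: bool = True
    joint_same_priority: bool = False
    backend: str = "auglag"
    inner_method: str = "lbfgs"       # "newton-cg" available
    rho0: float = 100.0
    rho_growth: float = 10.0
    max_outer_iter: int = 8
    newton_max_iter: int = 40
    cg_max_iter: int = 100
    newton_gtol: float = 1e-7
    max_inner_iter: int = 350         # per-outer L-BFGS budget
    lbfgs_memory: int = 20
    working_set_cap: int = 1500
    working_set_grow: int = 500

    def __post_init__(self):
        if self.delta < 1:
            raise ValueError("relaxation factor delta must be >= 1")
        if min(self.constraint_tol_gy, self.constraint_tol_rel) <= 0:
            raise ValueError("tolerances must be > 0")

    def gy_tol(self, limit: float) -> float:
        return max(self.constraint_tol_gy, self.constraint_tol_rel * abs(limit))


@dataclass
class StageRecord:
    """One subproblem of the lexicographic sweep."""

    pass_name: str          # "A", "B", or "tiebreak"
    priority: int
    label: str
    attained: float
    goal: Optional[float]
    bound: Optional[float]
    goal_met: Optional[bool]
    n_outer: int
    n_inner: int


@dataclass
class PlanResult:
    """Optimized fluence plus the full per-priority audit trail."""

    fluence: np.ndarray
    dose: np.ndarray
    trace: List[StageRecord]
    objective_values: Dict[str, float]       # label -> value in the final plan
    constraint_report: List[dict]            # hard-constraint slacks
    settings: SolverSettings
    diagnostics: dict = field(default_factory=dict)

    @property
    def all_hard_constraints_ok(self) -> bool:
        return all(e["ok"] for e in self.constraint_report)

    def trace_as_dicts(self) -> List[dict]:
        return [vars(r).copy() for r in self.trace]


@dataclass
class FeasibilityEntry:
    label: str
    kind: str
    limit: float
    violation: float


@dataclass
class FeasibilityReport:
    feasible: bool
    entries: List[FeasibilityEntry]

    @property
    def violated(self) -> List[FeasibilityEntry]:
        return [e for e in self.entries if e.violation > 0]


# --------------------------------------------------------------------------
# terms: cost functions bound to rows of the Dij matrix
# --------------------------------------------------------------------------



def _mv(M, v):
    """Sparse multiply in the matrix's own dtype (float32 matrices with
    float32 vectors are ~2x faster than mixed precision), returned as
    float64 for the optimizer."""
    return np.asarray(M @ np.asarray(v, dtype=M.dtype), dtype=np.float64)

class _Term:
    """A cost term over a fixed set of Dij rows.

    Provides the natural-unit value and, for smooth costs, a surrogate
    value/weight pair used inside the augmented Lagrangian: log-LTCP for
    LTCP (convex, well-scaled for alpha*D_p of order 50), the power mean
    for EUD, the dense mean row for MEAN.
    """

    def __init__(self, D_sub: sparse.csr_matrix, cost: CostSpec, label: str):
        self.D = D_sub
        self.m = D_sub.shape[0]
        self.cost = cost
        self.kind = cost.kind
        self.label = label
        self.c = np.asarray(D_sub.mean(axis=0)).ravel() if self.kind == "MEAN" else None

    def dose(self, x: np.ndarray) -> np.ndarray:
        return _mv(self.D, x)

    def value(self, x: np.ndarray, d: Optional[np.ndarray] = None) -> float:
        """Natural-unit value (LTCP is the plain LTCP, not its log)."""
        if self.kind == "MEAN":
            return float(self.c @ x)
        if d is None:
            d = self.dose(x)
        if self.kind == "MAX":
            return float(d.max())
        if self.kind == "LTCP":
            return float(np.exp(self.log_ltcp(d)))
        return self.eud(d)

    def surrogate(self, d: np.ndarray) -> Tuple[float, np.ndarray, dict]:
        """(phi, w, state): value, d(phi)/d(dose), and Hessian data."""
        if self.kind == "LTCP":
            a = self.cost.alpha
            e = -a * (d - self.cost.d_p)
            mx = e.max()
            ex = np.exp(e - mx)
            s = ex.sum()
            p = ex / s
            return float(mx + np.log(s) - np.log(self.m)), -a * p, {"p": p, "alpha": a}
        if self.kind == "EUD":
            val = self.eud(d)
            k = self.cost.k
            if val <= 0:
                z = np.zeros_like(d)
                return 0.0, z, {"E": 0.0, "k": k, "r": z, "w": z}
            r = np.maximum(d, 0.0) / val
            w = r ** (k - 1.0) / self.m
            return val, w, {"E": val, "k": k, "r": r, "w": w}
        raise AssertionError(f"no smooth surrogate for {self.kind}")  # pragma: no cover

    def surrogate_hvp(self, state: dict, u: np.ndarray) -> np.ndarray:
        """Hessian-vector product of the surrogate in dose space."""
        if self.kind == "LTCP":
            p, a = state["p"], state["alpha"]
            return a * a * (p * u - p * float(p @ u))
        E, k, r, w = state["E"], state["k"], state["r"], state["w"]
        if E <= 0 or k == 1:
            return np.zeros_like(u)
        if k >= 2:
            rk2 = r ** (k - 2.0)
        else:
            rk2 = np.where(r > 1e-12, r ** (k - 2.0), 0.0)
        return (k - 1.0) / E * (rk2 * u / self.m - w * float(w @ u))

    def surrogate_bound(self, natural_bound: float) -> float:
        if self.kind == "LTCP":
            return float(np.log(natural_bound))
        return float(natural_bound)

    def log_ltcp(self, d):
        return logsumexp(-self.cost.alpha * (d - self.cost.d_p)) - np.log(self.m)

    def eud(self, d):
        k = self.cost.k
        if k == 1:
            return float(d.mean())
        top = d.max()
        if top <= 0:
            return 0.0
        return float(top * np.mean((d / top) ** k) ** (1.0 / k))


class _Constraint:
    """A bound on a term: scalar (LTCP/EUD/MEAN) or per-voxel (MAX/MIN).

    Vector constraints carry a persistent working set ``W`` (positions
    into the term's rows) plus its dual variables; the full row list is
    checked against the incumbent at every outer iteration, so the
    reduction is exact at convergence.
    """

    def __init__(self, term: _Term, bound: float, tol: float, label: str,
                 hard: bool, sign: float = 1.0, settings: SolverSettings = None):
        self.term = term
        self.bound = float(bound)
        self.tol = float(tol)
        self.label = label
        self.hard = hard
        self.sign = float(sign)
        self.vector = term.kind == "MAX"
        self.settings = settings or SolverSettings()
        self.W: Optional[np.ndarray] = None
        self.lam: Optional[np.ndarray] = None
        if term.kind == "LTCP":
            self.scale = 1.0  # log units are already O(1)
        else:
            self.scale = max(1.0, abs(self.bound))

    def n_duals(self) -> int:
        return int(self.W.size) if self.vector else 1

    def reset_duals(self):
        self.lam = np.zeros(self.n_duals())

    def init_working_set(self, x: np.ndarray):
        if not self.vector:
            return
        cap = self.settings.working_set_cap
        if self.term.m <= cap:
            self.W = np.arange(self.term.m)  # small structure: exact rows
            return
        g = self.sign * (self.term.dose(x) - self.bound)
        margin = max(2 * self.tol, 0.05 * abs(self.bound))
        cand = np.nonzero(g >= -margin)[0]
        if cand.size > cap:
            cand = cand[np.argsort(-g[cand])[:cap]]
        if cand.size == 0:
            cand = np.argsort(-g)[: min(32, g.size)]
        self.W = np.sort(np.asarray(cand))

    def scaled_g(self, x: np.ndarray) -> np.ndarray:
        """Constraint function (working set for vectors), scaled."""
        if self.vector:
            d = _mv(self.term.D[self.W], x)
            return self.sign * (d - self.bound) / self.scale
        if self.term.kind == "MEAN":
            val = float(self.term.c @ x)
            return np.array([self.sign * (val - self.bound) / self.scale])
        d = self.term.dose(x)
        sval = self.term.surrogate(d)[0]
        return np.array([self.sign * (sval - self.term.surrogate_bound(self.bound)) / self.scale])

    def full_violation_and_grow(self, x: np.ndarray) -> Tuple[float, bool]:
        """Check ALL rows; grow the working set (padding duals); returns
        (violation in natural units, whether the set grew)."""
        if not self.vector:
            if self.term.kind == "MEAN":
                v = float(self.term.c @ x)
                return max(0.0, self.sign * (v - self.bound)), False
            d = self.term.dose(x)
            if self.term.kind == "LTCP":
                viol = float(self.term.log_ltcp(d) - np.log(self.bound))
            else:
                viol = self.sign * (self.term.value(x, d) - self.bound)
            return max(0.0, viol), False
        g = self.sign * (self.term.dose(x) - self.bound)
        viol = float(max(g.max(initial=-np.inf), 0.0))
        grew = False
        if viol > 0.5 * self.tol:
            bad = np.nonzero(g > 0.5 * self.tol)[0]
            outside = np.setdiff1d(bad, self.W)
            if outside.size:
                add = outside[np.argsort(-g[outside])[: self.settings.working_set_grow]]
                W_new = np.concatenate([self.W, add])
                lam_new = np.concatenate([self.lam, np.zeros(add.size)])
                order = np.argsort(W_new)
                self.W, self.lam = W_new[order], lam_new[order]
                grew = True
        return viol, grew


# --------------------------------------------------------------------------
# the augmented-Lagrangian stage solver
# --------------------------------------------------------------------------


class _Objective:
    """Stage objective: a 'smooth' term, 'maxvar' (epigraph max), joint
    'minmax' over goal-scaled terms, or the 'l2' fluence tie-break."""

    def __init__(self, kind: str, terms=None, scales=None, l2_weights=None):
        self.kind = kind
        self.terms = list(terms or [])
        self.scales = list(scales) if scales is not None else [1.0] * len(self.terms)
        self.l2_weights = l2_weights  # weights on z^2 (preconditioner^2)
        if self.needs_aux and any(t.kind == "LTCP" for t in self.terms):
            raise SolverError("joint priority slots with LTCP rows are not supported")

    @property
    def needs_aux(self) -> bool:
        return self.kind in ("maxvar", "minmax")

    def natural_value(self, x: np.ndarray) -> float:
        if self.kind == "l2":
            w = self.l2_weights if self.l2_weights is not None else 1.0
            return float(np.mean(w * x**2))
        if self.kind == "smooth":
            t = self.terms[0]
            return t.surrogate(t.dose(x))[0] if t.kind in ("LTCP", "EUD") else t.value(x)
        return max(t.value(x) / s for t, s in zip(self.terms, self.scales))


class _EpiPiece:
    """Epigraph coupling value/scale <= t for one objective term."""

    def __init__(self, term: _Term, scale: float, settings: SolverSettings):
        self.term = term
        self.scale = float(scale)
        self.settings = settings
        self.W: Optional[np.ndarray] = None   # working set for MAX terms
        self.lam = np.zeros(1)

    def init_working_set(self, x: np.ndarray, t: float):
        if self.term.kind != "MAX":
            self.lam = np.zeros(1)
            return
        cap = self.settings.working_set_cap
        if self.term.m <= cap:
            self.W = np.arange(self.term.m)
            self.lam = np.zeros(self.W.size)
            return
        d = self.term.dose(x) / self.scale
        margin = 0.05 * max(1.0, abs(t))
        cand = np.nonzero(d >= t - margin)[0]
        if cand.size > cap:
            cand = cand[np.argsort(-d[cand])[:cap]]
        if cand.size == 0:
            cand = np.argsort(-d)[: min(32, d.size)]
        self.W = np.sort(cand)
        self.lam = np.zeros(self.W.size)

    def full_violation_and_grow(self, x: np.ndarray, t: float, tol: float) -> Tuple[float, bool]:
        if self.term.kind != "MAX":
            val = (self.term.surrogate(self.term.dose(x))[0]
                   if self.term.kind == "EUD" else float(self.term.c @ x))
            return max(0.0, val / self.scale - t), False
        g = self.term.dose(x) / self.scale - t
        viol = float(max(g.max(initial=-np.inf), 0.0))
        grew = False
        if viol > 0.5 * tol:
            bad = np.nonzero(g > 0.5 * tol)[0]
            outside = np.setdiff1d(bad, self.W)
            if outside.size:
                add = outside[np.argsort(-g[outside])[: self.settings.working_set_grow]]
                W_new = np.concatenate([self.W, add])
                lam_new = np.concatenate([self.lam, np.zeros(add.size)])
                order = np.argsort(W_new)
                self.W, self.lam = W_new[order], lam_new[order]
                grew = True
        return viol, grew


def _projected_newton_cg(fun, hessp, hess_diag, y0, n_pos, settings) -> Tuple[np.ndarray, int]:
    """Minimize a smooth convex function subject to y[:n_pos] >= 0.

    Two-metric projection: bound-active coordinates (at zero with
    positive gradient) are frozen; a Jacobi-preconditioned truncated CG
    solve of the Newton system on the free coordinates gives the step
    (capped along near-zero-curvature directions), followed by a
    projected Armijo backtracking line search.  ``fun`` must return
    (value, gradient) and prime the state used by ``hessp``/``hess_diag``.
    """
    y = y0.copy()
    y[:n_pos] = np.maximum(y[:n_pos], 0.0)
    phi, g = fun(y)
    n_hvp = 0
    for _ in range(settings.newton_max_iter):
        act = np.zeros(y.size, bool)
        act[:n_pos] = (y[:n_pos] <= 1e-14) & (g[:n_pos] > 0)
        free = ~act
        gf = g[free]
        gnorm = float(np.linalg.norm(gf))
        if gnorm <= settings.newton_gtol * max(1.0, abs(phi)):
            break

        diag = np.maximum(hess_diag()[free], 1e-10)

        # preconditioned truncated CG on the free subspace
        b = -gf
        p = np.zeros_like(b)
        r = b.copy()
        zvec = r / diag
        d_dir = zvec.copy()
        rz = float(r @ zvec)
        cg_tol = min(0.25, np.sqrt(gnorm)) * np.sqrt(max(rz, 0.0))
        vfull = np.zeros(y.size)
        for _cg in range(settings.cg_max_iter):
            vfull[:] = 0.0
            vfull[free] = d_dir
            Hd = hessp(vfull)[free] + 1e-10 * diag * d_dir
            n_hvp += 1
            dHd = float(d_dir @ Hd)
            if dHd <= 0:
                break  # flat direction: keep the CG iterate found so far
            alpha = rz / dHd
            p += alpha * d_dir
            r -= alpha * Hd
            zvec = r / diag
            rz_new = float(r @ zvec)
            if np.sqrt(max(rz_new, 0.0)) <= cg_tol:
                break
            d_dir = zvec + (rz_new / rz) * d_dir
            rz = rz_new
        if not p.any() or float(p @ gf) >= 0:
            p = b / diag  # guaranteed descent fallback

        step = np.zeros(y.size)
        step[free] = p
        # projected Armijo backtracking (require genuine decrease)
        alpha = 1.0
        improved = False
        for _ls in range(30):
            y_new = y + alpha * step
            y_new[:n_pos] = np.maximum(y_new[:n_pos], 0.0)
            slope = float(g @ (y_new - y))
            phi_new, g_new = fun(y_new)
            if phi_new <= phi + 1e-4 * min(slope, 0.0) and phi_new < phi:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            fun(y)  # restore state at the incumbent
            break
        y, phi, g = y_new, phi_new, g_new
    return y, n_hvp


def _solve_stage(objective: _Objective, cons: List[_Constraint], x0: np.ndarray,
                 settings: SolverSettings) -> Tuple[np.ndarray, dict]:
    """One convex subproblem: min objective s.t. all constraints."""
    n = x0.size
    has_t = objective.needs_aux

    for c in cons:
        if c.vector and c.W is None:
            c.init_working_set(x0)
        c.reset_duals()

    # epigraph pieces; a bare max objective gets a scale so t stays O(1)
    if objective.kind == "maxvar" and objective.scales == [1.0]:
        objective.scales = [max(1.0, objective.terms[0].value(x0))]
    # start t slightly below the incumbent value so the epigraph penalty
    # is active from the first inner iteration (curvature in t)
    t_nat = objective.natural_value(np.maximum(x0, 0.0)) if has_t else 0.0
    t0 = t_nat - 0.02 * max(1.0, abs(t_nat)) if has_t else 0.0
    epi = []
    if has_t:
        for term, s in zip(objective.terms, objective.scales):
            piece = _EpiPiece(term, s, settings)
            piece.init_working_set(np.maximum(x0, 0.0), t0)
            epi.append(piece)

    s_f = max(1.0, abs(objective.natural_value(np.maximum(x0, 0.0))))
    y = np.concatenate([x0, [t0]]) if has_t else x0.copy()
    rho = settings.rho0
    total_inner = 0
    prev_worst = np.inf
    feasible_obj_prev = None
    status = "max_outer"
    n_outer = 0
    epi_tol = settings.constraint_tol_gy / max(s for s in objective.scales) if has_t else 0.0

    for outer in range(settings.max_outer_iter):
        n_outer = outer + 1

        # ---- assemble the stacked row matrix for this outer iteration
        blocks, row0 = [], 0

        def add_block(D_sub):
            nonlocal row0
            blocks.append(D_sub)
            sl = slice(row0, row0 + D_sub.shape[0])
            row0 += D_sub.shape[0]
            return sl

        obj_slice = None
        if objective.kind == "smooth" and objective.terms[0].kind != "MEAN":
            obj_slice = add_block(objective.terms[0].D)
        epi_slices = []
        for piece in epi:
            if piece.term.kind == "MAX":
                epi_slices.append(add_block(piece.term.D[piece.W]))
            elif piece.term.kind == "MEAN":
                epi_slices.append(None)
            else:
                epi_slices.append(add_block(piece.term.D))
        con_slices = []
        for c in cons:
            if c.vector:
                con_slices.append(add_block(c.term.D[c.W]))
            elif c.term.kind == "MEAN":
                con_slices.append(None)
            else:
                con_slices.append(add_block(c.term.D))
        M = sparse.vstack(blocks).tocsr() if blocks else sparse.csr_matrix((0, n))
        state: dict = {}

        def fun(yv):
            x = yv[:n]
            t = yv[n] if has_t else 0.0
            dall = _mv(M, x)
            w = np.zeros(M.shape[0])
            g_dense = np.zeros(n)
            g_t = 0.0
            phi = 0.0
            state.clear()
            state["x"] = x.copy()

            # objective
            if objective.kind == "l2":
                wv = objective.l2_weights if objective.l2_weights is not None else np.ones(n)
                phi += float(np.mean(wv * x**2)) / s_f
                g_dense += (2.0 / (n * s_f)) * (wv * x)
                state["l2w"] = wv
            elif objective.kind == "smooth":
                term = objective.terms[0]
                if term.kind == "MEAN":
                    phi += float(term.c @ x) / s_f
                    g_dense += term.c / s_f
                else:
                    val, wt, st = term.surrogate(dall[obj_slice])
                    phi += val / s_f
                    w[obj_slice] += wt / s_f
                    state["obj"] = st
            else:
                phi += t / s_f
                g_t += 1.0 / s_f

            # epigraph couplings
            epi_state = []
            for piece, sl in zip(epi, epi_slices):
                term, s, lam = piece.term, piece.scale, piece.lam
                if term.kind == "MAX":
                    g = dall[sl] / s - t
                    m_ = np.maximum(0.0, lam + rho * g)
                    phi += float(m_ @ m_ - lam @ lam) / (2 * rho)
                    w[sl] += m_ / s
                    g_t -= float(m_.sum())
                    epi_state.append({"m": m_})
                elif term.kind == "MEAN":
                    g = float(term.c @ x) / s - t
                    m_ = max(0.0, lam[0] + rho * g)
                    phi += (m_ * m_ - lam[0] ** 2) / (2 * rho)
                    g_dense += (m_ / s) * term.c
                    g_t -= m_
                    epi_state.append({"m": m_})
                else:  # EUD
                    val, wt, st = term.surrogate(dall[sl])
                    g = val / s - t
                    m_ = max(0.0, lam[0] + rho * g)
                    phi += (m_ * m_ - lam[0] ** 2) / (2 * rho)
                    w[sl] += (m_ / s) * wt
                    g_t -= m_
                    epi_state.append({"m": m_, "st": st, "w": wt})
            state["epi"] = epi_state

            # constraints
            con_state = []
            for c, sl in zip(cons, con_slices):
                lam = c.lam
                if c.vector:
                    g = c.sign * (dall[sl] - c.bound) / c.scale
                    m_ = np.maximum(0.0, lam + rho * g)
                    phi += float(m_ @ m_ - lam @ lam) / (2 * rho)
                    w[sl] += (c.sign / c.scale) * m_
                    con_state.append({"m": m_})
                elif c.term.kind == "MEAN":
                    g = c.sign * (float(c.term.c @ x) - c.bound) / c.scale
                    m_ = max(0.0, lam[0] + rho * g)
                    phi += (m_ * m_ - lam[0] ** 2) / (2 * rho)
                    g_dense += (m_ * c.sign / c.scale) * c.term.c
                    con_state.append({"m": m_})
                else:
                    val, wt, st = c.term.surrogate(dall[sl])
                    g = c.sign * (val - c.term.surrogate_bound(c.bound)) / c.scale
                    m_ = max(0.0, lam[0] + rho * g)
                    phi += (m_ * m_ - lam[0] ** 2) / (2 * rho)
                    w[sl] += (m_ * c.sign / c.scale) * wt
                    con_state.append({"m": m_, "st": st, "w": wt})
            state["con"] = con_state

            grad_x = _mv(M.T, w) + g_dense
            if has_t:
                return phi, np.concatenate([grad_x, [g_t]])
            return phi, grad_x

        def hessp(v):
            """Hessian-vector product at the last point ``fun`` evaluated."""
            vx = v[:n]
            vt = v[n] if has_t else 0.0
            u = _mv(M, vx)
            hw = np.zeros(M.shape[0])
            h_dense = np.zeros(n)
            h_t = 0.0

            if objective.kind == "l2":
                h_dense += (2.0 / (n * s_f)) * state["l2w"] * vx
            elif objective.kind == "smooth" and obj_slice is not None:
                term = objective.terms[0]
                hw[obj_slice] += term.surrogate_hvp(state["obj"], u[obj_slice]) / s_f

            for piece, sl, pst in zip(epi, epi_slices, state["epi"]):
                term, s = piece.term, piece.scale
                if term.kind == "MAX":
                    m_ = pst["m"]
                    act = m_ > 0
                    ju = np.where(act, u[sl] / s - vt, 0.0)
                    hw[sl] += rho * ju / s
                    h_t -= rho * float(ju.sum())
                elif term.kind == "MEAN":
                    if pst["m"] > 0:
                        ju = float(term.c @ vx) / s - vt
                        h_dense += (rho * ju / s) * term.c
                        h_t -= rho * ju
                else:
                    wt = pst["w"]
                    if pst["m"] > 0:
                        ju = float(wt @ u[sl]) / s - vt
                        hw[sl] += (rho * ju / s) * wt
                        h_t -= rho * ju
                    hw[sl] += (pst["m"] / s) * term.surrogate_hvp(pst["st"], u[sl])

            for c, sl, cst in zip(cons, con_slices, state["con"]):
                if c.vector:
                    act = cst["m"] > 0
                    hw[sl] += (rho / c.scale**2) * np.where(act, u[sl], 0.0)
                elif c.term.kind == "MEAN":
                    if cst["m"] > 0:
                        h_dense += (rho / c.scale**2) * float(c.term.c @ vx) * c.term.c
                else:
                    wt = cst["w"]
                    if cst["m"] > 0:
                        hw[sl] += (rho / c.scale**2) * float(wt @ u[sl]) * wt
                    hw[sl] += (cst["m"] / c.scale) * c.term.surrogate_hvp(cst["st"], u[sl])

            hx = _mv(M.T, hw) + h_dense
            if has_t:
                return np.concatenate([hx, [h_t]])
            return hx

        M2 = None

        def hess_diag():
            """Approximate Hessian diagonal (Jacobi preconditioner)."""
            nonlocal M2
            if M2 is None:
                M2 = M.power(2).tocsr()
            hwd = np.zeros(M.shape[0])
            dd = np.full(n, 1e-12)
            td = 1e-12

            def smooth_diag(term, st):
                if term.kind == "LTCP":
                    return st["alpha"] ** 2 * st["p"]
                E, k, r = st["E"], st["k"], st["r"]
                if E <= 0 or k == 1:
                    return 0.0
                rk2 = r ** (k - 2.0) if k >= 2 else np.where(r > 1e-12, r ** (k - 2.0), 0.0)
                return (k - 1.0) / E * rk2 / term.m

            if objective.kind == "l2":
                dd += (2.0 / (n * s_f)) * state["l2w"]
            elif objective.kind == "smooth" and obj_slice is not None:
                hwd[obj_slice] += smooth_diag(objective.terms[0], state["obj"]) / s_f
            for piece, sl, pst in zip(epi, epi_slices, state["epi"]):
                term, s = piece.term, piece.scale
                if term.kind == "MAX":
                    actv = pst["m"] > 0
                    hwd[sl] += (rho / s**2) * actv
                    td += rho * float(actv.sum())
                elif term.kind == "MEAN":
                    if pst["m"] > 0:
                        dd += (rho / s**2) * term.c**2
                        td += rho
                else:
                    if pst["m"] > 0:
                        hwd[sl] += (rho / s**2) * pst["w"] ** 2
                        td += rho
                    hwd[sl] += (pst["m"] / s) * smooth_diag(term, pst["st"])
            for c, sl, cst in zip(cons, con_slices, state["con"]):
                if c.vector:
                    hwd[sl] += (rho / c.scale**2) * (cst["m"] > 0)
                elif c.term.kind == "MEAN":
                    if cst["m"] > 0:
                        dd += (rho / c.scale**2) * c.term.c**2
                else:
                    if cst["m"] > 0:
                        hwd[sl] += (rho / c.scale**2) * cst["w"] ** 2
                    hwd[sl] += (cst["m"] / c.scale) * smooth_diag(c.term, cst["st"])
            dvec = _mv(M2.T, hwd) + dd
            if has_t:
                return np.concatenate([dvec, [td]])
            return dvec

        if settings.inner_method == "newton-cg":
            y, n_hvp = _projected_newton_cg(fun, hessp, hess_diag, y, n, settings)
            total_inner += n_hvp
        else:
            bounds = [(0.0, None)] * n + ([(None, None)] if has_t else [])
            # restart on premature f-tolerance stops at the penalty wall
            # (fresh quasi-Newton memory usually un-sticks the iteration)
            budget = settings.max_inner_iter
            for _restart in range(3):
                res = optimize.minimize(
                    fun, y, jac=True, method="L-BFGS-B", bounds=bounds,
                    options=dict(maxiter=budget, maxcor=settings.lbfgs_memory,
                                 maxls=40, ftol=1e-14, gtol=1e-8))
                y = res.x
                total_inner += int(res.nit)
                budget -= int(res.nit)
                if budget <= 10:
                    break
                phi_chk, g_chk = fun(y)
                pg = g_chk.copy()
                at_bound = (y[:n] <= 1e-14) & (g_chk[:n] > 0)
                pg[:n][at_bound] = 0.0
                if np.abs(pg).max() <= 1e-5 * max(1.0, abs(phi_chk)):
                    break

        x = np.maximum(y[:n], 0.0)
        t = y[n] if has_t else 0.0

        # ---- full-row feasibility check; grow working sets where needed
        worst = 0.0
        grew_any = False
        for c in cons:
            viol, grew = c.full_violation_and_grow(x)
            worst = max(worst, viol / max(c.tol, 1e-300))
            grew_any |= grew
        for piece in epi:
            viol, grew = piece.full_violation_and_grow(x, t, epi_tol)
            worst = max(worst, viol / max(epi_tol, 1e-300))
            grew_any |= grew
        if worst <= 1.0 and not grew_any:
            # feasible; accept only once the objective has settled, so a
            # stage cannot stop at the first feasible iterate with
            # immature duals (continue with one more multiplier update)
            obj_now = objective.natural_value(x)
            if feasible_obj_prev is not None and (
                    feasible_obj_prev - obj_now <= 5e-4 * max(1.0, abs(obj_now))):
                status = "converged"
                break
            feasible_obj_prev = obj_now

        if grew_any:
            # the inner solve ran against an incomplete row set: re-solve
            # with the grown set before touching duals or the penalty
            prev_worst = worst
            continue

        # ---- safeguarded updates: accept the dual step only when the
        # violation improved sufficiently, else stiffen the penalty
        if worst <= max(1.0, 0.25 * prev_worst):
            for c in cons:
                c.lam = np.maximum(0.0, c.lam + rho * c.scaled_g(x))
            for piece in epi:
                term, s = piece.term, piece.scale
                if term.kind == "MAX":
                    g = _mv(term.D[piece.W], x) / s - t
                elif term.kind == "MEAN":
                    g = np.array([float(term.c @ x) / s - t])
                else:
                    g = np.array([term.surrogate(term.dose(x))[0] / s - t])
                piece.lam = np.maximum(0.0, piece.lam + rho * g)
        else:
            rho = min(rho * settings.rho_growth, 1e9)
        prev_worst = worst

    x_final = np.maximum(y[:n], 0.0)
    violations = {}
    if status != "converged":
        for c in cons:
            viol, _ = c.full_violation_and_grow(x_final)
            if viol > c.tol:
                violations[c.label] = (c, viol)
    info = {"status": status, "n_outer": n_outer, "n_inner": total_inner,
            "max_scaled_violation": float(prev_worst if status != "converged" else 0.0),
            "violations": violations}
    return x_final, info


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------


def _dij_rows(dij: DoseInfluenceMatrix, flat_voxels: np.ndarray) -> np.ndarray:
    inv = np.full(dij.grid.n_voxels, -1, dtype=np.int64)
    inv[dij.voxel_index] = np.arange(dij.voxel_index.size)
    rows = inv[np.asarray(flat_voxels)]
    return rows[rows >= 0]


def _column_equilibration(D: sparse.csr_matrix) -> np.ndarray:
    """Per-beamlet scale factors p with unit-norm scaled columns.

    The optimizer works in z = x / p; this diagonal preconditioning
    equalizes the sensitivity of central and grazing beamlets.
    """
    norms = np.sqrt(np.asarray(D.power(2).sum(axis=0)).ravel())
    norms[norms == 0] = 1.0
    return 1.0 / norms


def _build_terms(dij, problem, col_scale: Optional[np.ndarray] = None):
    """Terms for every hard constraint and objective row.

    If ``col_scale`` is given, term matrices act on the preconditioned
    variable z (columns of Dij scaled by it), so x = col_scale * z.
    """
    sub_cache: Dict[str, sparse.csr_matrix] = {}
    base = dij.matrix
    if col_scale is not None:
        # keep the matrix dtype (float32 Dij stays float32 end to end)
        base = (base @ sparse.diags(col_scale.astype(base.dtype))).tocsr()

    def submatrix(structure, voxels):
        if structure not in sub_cache:
            sub_cache[structure] = base[_dij_rows(dij, voxels)].tocsr()
        return sub_cache[structure]

    hard = []
    for c in problem.constraints:
        cost = CostSpec(kind="MAX" if c.kind in ("MAX", "MIN") else "MEAN")
        hard.append((c, _Term(submatrix(c.structure, c.voxels), cost, c.label)))
    objs = []
    for o in problem.objectives:
        objs.append((o, _Term(submatrix(o.structure, o.voxels), o.cost, o.label)))
    return hard, objs


def feasibility_check(dij: DoseInfluenceMatrix, problem: ResolvedProblem,
                      settings: SolverSettings = None) -> FeasibilityReport:
    """Min-slack feasibility of the hard constraints.

    Upper-bound-only constraint sets (the packaged wishlists) are feasible
    at zero fluence by construction; when lower bounds (MIN) are present a
    least-violation fluence is sought by minimizing the total squared
    violation, and per-constraint violations at that point are reported.
    """
    settings = settings or SolverSettings()
    hard, _ = _build_terms(dij, problem)
    has_lower = any(c.kind == "MIN" for c, _ in hard)

    if not has_lower:
        entries = [FeasibilityEntry(c.label, c.kind, c.limit_gy, 0.0) for c, _ in hard]
        return FeasibilityReport(True, entries)

    n = dij.n_beamlets

    def fun(x):
        phi = 0.0
        g = np.zeros(n)
        for c, term in hard:
            sign = -1.0 if c.kind == "MIN" else 1.0
            s = max(1.0, abs(c.limit_gy))
            if term.kind == "MEAN":
                v = sign * (float(term.c @ x) - c.limit_gy) / s
                if v > 0:
                    phi += v * v
                    g += (2 * v * sign / s) * term.c
            else:
                v = sign * (term.dose(x) - c.limit_gy) / s
                pos = v > 0
                if pos.any():
                    phi += float(v[pos] @ v[pos])
                    w = np.where(pos, 2 * v * sign / s, 0.0)
                    g += _mv(term.D.T, w)
        return phi, g

    res = optimize.minimize(fun, np.ones(n), jac=True, method="L-BFGS-B",
                            bounds=[(0, None)] * n,
                            options=dict(maxiter=800, ftol=1e-15, gtol=1e-12))
    x = res.x
    entries, feasible = [], True
    for c, term in hard:
        sign = -1.0 if c.kind == "MIN" else 1.0
        if term.kind == "MEAN":
            v = sign * (float(term.c @ x) - c.limit_gy)
        else:
            v = float((sign * (term.dose(x) - c.limit_gy)).max(initial=-np.inf))
        viol = max(0.0, v)
        if viol > settings.gy_tol(c.limit_gy):
            feasible = False
        entries.append(FeasibilityEntry(c.label, c.kind, c.limit_gy, viol))
    return FeasibilityReport(feasible, entries)


def _initial_fluence(objs, n: int) -> np.ndarray:
    """Uniform fluence scaled so the first LTCP target's mean dose = D_p."""
    u = np.ones(n)
    for o, term in objs:
        if o.cost.kind == "LTCP":
            mean_d = float(term.dose(u).mean())
            if mean_d > 0:
                return (o.cost.d_p / mean_d) * u
    return u


def solve_prioritized(dij: DoseInfluenceMatrix, problem: ResolvedProblem,
                      settings: SolverSettings = None) -> PlanResult:
    """Run the full two-pass prioritized optimization; see module docstring."""
    settings = settings or SolverSettings()
    feas = feasibility_check(dij, problem, settings)
    if not feas.feasible:
        names = ", ".join(e.label for e in feas.violated)
        raise InfeasibleProblemError(
            f"hard constraints are infeasible: {names}", report=feas)

    col_scale = _column_equilibration(dij.matrix)
    hard, objs = _build_terms(dij, problem, col_scale)

    cons: List[_Constraint] = []
    for c, term in hard:
        sign = -1.0 if c.kind == "MIN" else 1.0
        cons.append(_Constraint(term, c.limit_gy, settings.gy_tol(c.limit_gy),
                                c.label, hard=True, sign=sign, settings=settings))

    x = _initial_fluence(objs, dij.n_beamlets)
    # project the warm start onto the (linear, upper-bound) hard limits so
    # every stage inherits a feasible incumbent
    shrink = 1.0
    for c, term in hard:
        if c.kind == "MIN":
            continue
        val = term.value(x)
        if val > c.limit_gy:
            shrink = min(shrink, c.limit_gy / val)
    x = x * shrink * (1.0 - 1e-9)
    trace: List[StageRecord] = []
    bound_cons: Dict[int, _Constraint] = {}  # objective order -> its bound

    def tol_for(o):
        if o.cost.kind == "LTCP":
            # expressed in log units so it matches the Gy tolerance:
            # d(log LTCP) = alpha * d(dose) for a uniform shift
            return max(settings.ltcp_log_tol,
                       o.cost.alpha * settings.gy_tol(o.cost.d_p))
        return settings.gy_tol(max(o.goal, 1.0))

    def worst_violation(active_cons, x):
        out = 0.0
        for c in active_cons:
            viol, _ = c.full_violation_and_grow(x)
            out = max(out, viol / max(c.tol, 1e-300))
        return out

    def run_stage(o, term, active_cons, x_start, stage_settings=None):
        st = stage_settings or settings
        t_start = time.perf_counter()
        objective = (_Objective("maxvar", [term]) if o.cost.kind == "MAX"
                     else _Objective("smooth", [term]))
        x_new, info = _solve_stage(objective, active_cons, x_start, st)
        if info["status"] != "converged" and any(
                c.hard for c, _ in info["violations"].values()):
            # a second attempt with a stiffer penalty schedule whenever a
            # hard constraint is at stake (these stages typically sit on
            # the LTCP-bound / mean-cap knife edge and need settled duals)
            import dataclasses as _dc
            boosted = _dc.replace(st, rho0=st.rho0 * 30,
                                  max_outer_iter=2 * st.max_outer_iter)
            x_new, info = _solve_stage(objective, active_cons, x_new, boosted)
        if info["status"] != "converged" and info["violations"]:
            # Restore feasibility without ever weakening earlier bounds
            # (that would invert the priority order).  First try the exact
            # linear repair for upper-bound hard limits, then backtrack
            # toward the incumbent, which satisfies every active
            # constraint by induction.
            hard_bad = {lbl: (c, v) for lbl, (c, v) in info["violations"].items()
                        if c.hard}
            if hard_bad and all(c.sign > 0 for c, _ in hard_bad.values()):
                factor = min(c.bound / (c.bound + v) for c, v in hard_bad.values())
                x_try = x_new * factor * (1.0 - 1e-9)
                if worst_violation(active_cons, x_try) <= 1.0:
                    x_new = x_try
                    log.info("stage %s: rescaled fluence by %.5f to restore %s",
                             o.label, factor, sorted(hard_bad))
            if worst_violation(active_cons, x_new) > 1.0:
                for alpha in (0.6, 0.35, 0.2, 0.1, 0.05, 0.0):
                    x_try = alpha * x_new + (1.0 - alpha) * x_start
                    if worst_violation(active_cons, x_try) <= 1.0:
                        log.warning(
                            "stage %s: backtracked to alpha=%.2f to keep all "
                            "imposed bounds", o.label, alpha)
                        x_new = x_try
                        break
                else:
                    raise SolverError(
                        f"stage {o.label!r} cannot restore feasibility "
                        f"(scaled violation {info['max_scaled_violation']:.3g})",
                        priority=o.priority)
        log.info("stage %-32s %6.1fs outer=%d hvp=%d attained=%.4g",
                 o.label, time.perf_counter() - t_start,
                 info["n_outer"], info["n_inner"], term.value(x_new))
        return x_new, term.value(x_new), info

    def impose_bound(o, term, attained):
        goal_met = attained <= o.goal * (1 + 1e-9) + 1e-12
        bound = o.goal if goal_met else attained * settings.delta
        con = _Constraint(term, bound, tol_for(o), f"bound[{o.label}]",
                          hard=False, settings=settings)
        cons.append(con)
        bound_cons[o.order] = con
        return bound, goal_met

    # ---- Pass A: impose bounds in priority order ----------------------
    if settings.joint_same_priority:
        by_priority: Dict[int, list] = {}
        for o, term in objs:
            by_priority.setdefault(o.priority, []).append((o, term))
        for priority in sorted(by_priority):
            slot = by_priority[priority]
            if len(slot) == 1:
                o, term = slot[0]
                x, attained, info = run_stage(o, term, cons, x)
                bound, met = impose_bound(o, term, attained)
                trace.append(StageRecord("A", priority, o.label, attained, o.goal,
                                         bound, met, info["n_outer"], info["n_inner"]))
            else:
                objective = _Objective("minmax", [t for _, t in slot],
                                       [o.goal for o, _ in slot])
                x, info = _solve_stage(objective, cons, x, settings)
                for o, term in slot:
                    attained = term.value(x)
                    bound, met = impose_bound(o, term, attained)
                    trace.append(StageRecord("A", priority, o.label, attained,
                                             o.goal, bound, met,
                                             info["n_outer"], info["n_inner"]))
    else:
        for o, term in objs:
            x, attained, info = run_stage(o, term, cons, x)
            bound, met = impose_bound(o, term, attained)
            trace.append(StageRecord("A", o.priority, o.label, attained, o.goal,
                                     bound, met, info["n_outer"], info["n_inner"]))

    # ---- Pass B: tighten each bound to its attainable value ------------
    if settings.tighten_pass:
        import dataclasses as _dc
        # warm-started refinements: a reduced budget suffices here
        tighten_settings = _dc.replace(
            settings,
            max_outer_iter=min(settings.max_outer_iter, 4),
            max_inner_iter=min(settings.max_inner_iter, 250))
        for o, term in objs:
            own = bound_cons[o.order]
            active = [c for c in cons if c is not own]
            x, attained, info = run_stage(o, term, active, x, tighten_settings)
            margin = (attained * 2e-4) if o.cost.kind == "LTCP" else 0.25 * tol_for(o)
            own.bound = attained + margin
            own.scale = max(1.0, abs(own.bound)) if o.cost.kind != "LTCP" else 1.0
            own.W = None  # the bound moved: rebuild the working set
            trace.append(StageRecord("B", o.priority, o.label, attained, o.goal,
                                     own.bound, attained <= o.goal * (1 + 1e-9),
                                     info["n_outer"], info["n_inner"]))

    # ---- tie-break: minimum-norm fluence among the near-optima ---------
    import dataclasses as _dc
    tb_settings = _dc.replace(settings, max_outer_iter=min(settings.max_outer_iter, 4),
                              max_inner_iter=min(settings.max_inner_iter, 250))
    x_tb, info = _solve_stage(_Objective("l2", l2_weights=col_scale**2), cons, x, tb_settings)
    if info["status"] == "converged" and worst_violation(cons, x_tb) <= 1.0:
        x = x_tb
    trace.append(StageRecord("tiebreak", 0, "fluence l2-norm",
                             float(np.mean((col_scale * x) ** 2)),
                             None, None, None, info["n_outer"], info["n_inner"]))

    # ---- final audit ---------------------------------------------------
    fluence = col_scale * x
    dose = dij.dose_from_fluence(fluence)
    objective_values = {o.label: term.value(x) for o, term in objs}
    report = []
    for c, term in hard:
        val = term.value(x)
        sign = -1.0 if c.kind == "MIN" else 1.0
        slack = sign * (c.limit_gy - val)
        tol = settings.gy_tol(c.limit_gy)
        report.append({"label": c.label, "structure": c.structure, "kind": c.kind,
                       "limit_gy": c.limit_gy, "value_gy": val,
                       "slack_gy": slack, "ok": bool(slack >= -tol)})
    bad = [e["label"] for e in report if not e["ok"]]
    if bad:
        raise SolverError(f"final plan violates hard constraints: {', '.join(bad)}")

    return PlanResult(
        fluence=fluence, dose=dose, trace=trace,
        objective_values=objective_values, constraint_report=report,
        settings=settings,
        diagnostics={"n_beamlets": dij.n_beamlets, "n_voxels": dij.n_voxels,
                     "n_stages": len(trace)},
    )
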