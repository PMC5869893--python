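"""Wishlist data model, (de)serialization, and resolution.

A wishlist is an ordered planning protocol: a set of hard constraints
that the optimizer must never violate, plus objectives with priorities
that are minimized one after another (the prioritized epsilon-constraint
method).  The two packaged configs (``wprt_phase1.yaml``,
``wprt_phase2.yaml``) encode the published whole-pelvis protocol: phase 1
treats PTV-P to 60 Gy and PTV-LN to 50 Gy as a simultaneous integrated
boost, phase 2 boosts PTV-P by 13 Gy.

Dose limits and goals may be absolute (Gy) or percentages of a named
prescription reference (``D_high`` = 60 Gy, ``D_low`` = 50 Gy, ``D_p`` =
13 Gy boost); :func:`resolve` converts everything to absolute Gy against
a :class:`PrescriptionContext` and materializes the auxiliary structures
(fall-off shells, skin ring, transition region, unspecified tissue) the
protocol refers to.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import geometry
from .costs import CostSpec
from .errors import StructureError
from .grid import StructureSet, VoxelGrid

log = logging.getLogger(__name__)

DoseRefName = Literal["D_high", "D_low", "D_p"]


class PrescriptionContext(BaseModel):
    """Prescribed dose levels and fraction counts of the two-phase protocol."""

    d_high: float = 60.0   # phase-1 dose to PTV-P (Gy)
    d_low: float = 50.0    # phase-1 dose to PTV-LN (Gy)
    d_boost: float = 13.0  # phase-2 boost dose to PTV-P (Gy)
    fractions_phase1: int = 25
    fractions_phase2: int = 5

    @model_validator(mode="after")
    def _positive(self):
        if min(self.d_high, self.d_low, self.d_boost) <= 0:
            raise ValueError("prescription doses must be > 0")
        if min(self.fractions_phase1, self.fractions_phase2) < 1:
            raise ValueError("fraction counts must be >= 1")
        return self

    def reference(self, name: DoseRefName) -> float:
        return {"D_high": self.d_high, "D_low": self.d_low, "D_p": self.d_boost}[name]

    @property
    def total_fractions(self) -> int:
        return self.fractions_phase1 + self.fractions_phase2

    @property
    def summed_prescription_ptv_p(self) -> float:
        return self.d_high + self.d_boost

    @property
    def summed_prescription_ptv_ln(self) -> float:
        return self.d_low


class Quantity(BaseModel):
    """A dose limit/goal: absolute Gy, percent of a reference, or unitless."""

    model_config = ConfigDict(extra="forbid")

    gy: Optional[float] = None
    percent: Optional[float] = None
    of: Optional[DoseRefName] = None
    value: Optional[float] = None  # unitless (LTCP goals)

    @model_validator(mode="after")
    def _exactly_one(self):
        forms = [self.gy is not None, self.percent is not None, self.value is not None]
        if sum(forms) != 1:
            raise ValueError("specify exactly one of gy / percent / value")
        if (self.percent is None) != (self.of is None):
            raise ValueError("'percent' and 'of' must be given together")
        for v in (self.gy, self.percent, self.value):
            if v is not None and v <= 0:
                raise ValueError("limits and goals must be > 0")
        return self

    def resolve(self, ctx: PrescriptionContext) -> float:
        if self.gy is not None:
            return self.gy
        if self.percent is not None:
            return self.percent / 100.0 * ctx.reference(self.of)
        return self.value

    @property
    def is_unitless(self) -> bool:
        return self.value is not None


class CostModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["LTCP", "EUD", "MAX", "MEAN"]
    d_p: Optional[Quantity] = None
    alpha: Optional[float] = Field(default=None, gt=0)
    k: Optional[float] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _params(self):
        if self.kind == "LTCP" and (self.d_p is None or self.alpha is None):
            raise ValueError("LTCP requires d_p and alpha")
        if self.kind == "EUD" and self.k is None:
            raise ValueError("EUD requires the volume-effect exponent k")
        return self

    def resolve(self, ctx: PrescriptionContext) -> CostSpec:
        return CostSpec(
            kind=self.kind,
            d_p=self.d_p.resolve(ctx) if self.d_p is not None else None,
            alpha=self.alpha,
            k=self.k,
        )


class HardConstraint(BaseModel):
    model_config = ConfigDict(extra="forbid")

    structure: str
    type: Literal["MAX", "MEAN", "MIN"]
    limit: Quantity


class PrioritizedObjective(BaseModel):
    model_config = ConfigDict(extra="forbid")

    priority: int = Field(ge=1)
    structure: str
    cost: CostModel
    goal: Quantity


class AuxiliaryRecipes(BaseModel):
    """How the wishlist's derived structures are built from the base set."""

    model_config = ConfigDict(extra="forbid")

    shell_target: str = "PTV-LN"
    shell_distances_mm: List[float] = Field(default_factory=lambda: [5.0, 15.0, 25.0, 50.0])
    shell_thickness_mm: float = Field(default=5.0, gt=0)
    shell_mode: Literal["band", "beyond"] = "band"
    skin_ring_depth_mm: float = Field(default=20.0, gt=0)
    transition_margin_mm: float = Field(default=5.0, ge=0)


class Wishlist(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    name: str
    phase: int = Field(ge=1, le=2)
    description: str = ""
    auxiliary: AuxiliaryRecipes = Field(default_factory=AuxiliaryRecipes)
    constraints: List[HardConstraint]
    objectives: List[PrioritizedObjective]

    @model_validator(mode="after")
    def _ordered(self):
        if not self.objectives:
            raise ValueError("a wishlist needs at least one objective")
        prios = [o.priority for o in self.objectives]
        if prios != sorted(prios):
            raise ValueError("objectives must be listed in non-decreasing priority order")
        return self

    @property
    def phase_target(self) -> str:
        return "PTV-LN" if self.phase == 1 else "PTV-P"

    @property
    def phase_prescription_ref(self) -> DoseRefName:
        return "D_high" if self.phase == 1 else "D_p"


def builtin_wishlist(phase: int) -> Wishlist:
    """The packaged whole-pelvis (phase 1) or boost (phase 2) wishlist."""
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    text = resources.files("lexiplan.data").joinpath(f"wprt_phase{phase}.yaml").read_text()
    return Wishlist.model_validate(yaml.safe_load(text))


def load_wishlist(path) -> Wishlist:
    return Wishlist.model_validate(yaml.safe_load(Path(path).read_text()))


def save_wishlist(wishlist: Wishlist, path):
    Path(path).write_text(
        yaml.safe_dump(wishlist.model_dump(exclude_none=True), sort_keys=False)
    )


# --------------------------------------------------------------------------
# resolution: symbolic wishlist -> absolute-Gy problem bound to voxels
# --------------------------------------------------------------------------

_SHELL_RE = re.compile(r"^(?P<target>.+?) shell (?P<dist>\d+(?:\.\d+)?) mm$")
_RING_RE = re.compile(r"^Skin ring (?P<depth>\d+(?:\.\d+)?) mm$")
_MINUS_RE = re.compile(r"^(?P<a>.+?) - (?P<b>.+?)\+(?P<margin>\d+(?:\.\d+)?)mm$")
_FEM_RE = re.compile(r"^Left\+right femoral head$")
_UNSPEC_RE = re.compile(r"^Unspecified tissues?$")


@dataclass(frozen=True)
class ResolvedConstraint:
    label: str
    structure: str
    kind: str          # MAX / MEAN / MIN
    limit_gy: float
    voxels: np.ndarray  # flat grid indices


@dataclass(frozen=True)
class ResolvedObjective:
    priority: int
    order: int          # position within the wishlist (stable tiebreak)
    label: str
    structure: str
    cost: CostSpec
    goal: float         # absolute Gy, or unitless for LTCP
    voxels: np.ndarray


@dataclass
class ResolvedProblem:
    """A wishlist bound to a structure set and prescription context."""

    wishlist_name: str
    phase: int
    context: PrescriptionContext
    grid: VoxelGrid
    constraints: List[ResolvedConstraint]
    objectives: List[ResolvedObjective]
    aux_masks: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def priorities(self) -> List[int]:
        return sorted({o.priority for o in self.objectives})


def _materialize(name: str, structures: StructureSet, aux: AuxiliaryRecipes,
                 cache: Dict[str, np.ndarray]) -> np.ndarray:
    """Build (and cache) the mask for a wishlist structure name."""
    if name in cache:
        return cache[name]
    grid = structures.grid
    external = structures["external"]

    if name in structures:
        mask = structures[name]
    elif _FEM_RE.match(name):
        mask = structures["femoral_head_left"] | structures["femoral_head_right"]
    elif (m := _SHELL_RE.match(name)):
        target = _materialize(m["target"], structures, aux, cache)
        dist = float(m["dist"])
        if aux.shell_mode == "band":
            mask = geometry.shell(target, dist, grid, external, aux.shell_thickness_mm)
        else:
            mask = geometry.expansion_beyond(target, dist, grid, external)
        # fall-off shells never overlap the phase targets
        for t in ("PTV-LN", "PTV-P"):
            if t in structures:
                mask = geometry.subtract(mask, structures[t])
    elif (m := _RING_RE.match(name)):
        mask = geometry.inner_ring(external, float(m["depth"]), grid)
        for t in ("PTV-LN", "PTV-P"):
            if t in structures:
                mask = geometry.subtract(mask, structures[t])
    elif (m := _MINUS_RE.match(name)):
        a = _materialize(m["a"], structures, aux, cache)
        b = _materialize(m["b"], structures, aux, cache)
        mask = geometry.subtract(a, geometry.expand(b, float(m["margin"]), grid))
    elif _UNSPEC_RE.match(name):
        raise RuntimeError("unspecified tissue is materialized last")  # pragma: no cover
    else:
        raise StructureError(f"cannot resolve structure {name!r}: no mask and no recipe")
    cache[name] = mask
    return mask


def resolve(
    wishlist: Wishlist,
    context: PrescriptionContext,
    structures: StructureSet,
) -> ResolvedProblem:
    """Convert limits to Gy, build auxiliaries, bind rows to voxel lists.

    Pure and idempotent: the same inputs always give the same problem.
    Rows whose structure comes out empty on this grid are dropped with a
    warning; a name with neither a mask nor a recipe raises
    :class:`StructureError`.
    """
    cache: Dict[str, np.ndarray] = {}
    names = [c.structure for c in wishlist.constraints] + [o.structure for o in wishlist.objectives]
    unspec_names = [n for n in names if _UNSPEC_RE.match(n)]
    for n in names:
        if not _UNSPEC_RE.match(n):
            _materialize(n, structures, wishlist.auxiliary, cache)

    if unspec_names:
        # everything named anywhere (base structures + auxiliaries) is "specified"
        claimed = [m for n, m in structures.masks.items() if n != "external"]
        claimed += list(cache.values())
        unspec = geometry.unspecified_tissue(structures["external"], claimed)
        for n in unspec_names:
            cache[n] = unspec

    def rows(name):
        return np.flatnonzero(cache[name])

    constraints = []
    for c in wishlist.constraints:
        vox = rows(c.structure)
        limit = c.limit.resolve(context)
        label = f"{c.structure} {c.type} <= {limit:.4g} Gy"
        if vox.size == 0:
            log.warning("dropping hard constraint on empty structure %r", c.structure)
            continue
        constraints.append(ResolvedConstraint(label, c.structure, c.type, limit, vox))

    objectives = []
    for i, o in enumerate(wishlist.objectives):
        vox = rows(o.structure)
        if vox.size == 0:
            log.warning("dropping objective on empty structure %r", o.structure)
            continue
        cost = o.cost.resolve(context)
        goal = o.goal.resolve(context)
        if cost.kind == "LTCP" and not o.goal.is_unitless:
            raise ValueError(f"LTCP goals are unitless, got {o.goal!r}")
        label = f"p{o.priority} {o.structure} {cost.kind}"
        objectives.append(ResolvedObjective(o.priority, i, label, o.structure, cost, goal, vox))

    return ResolvedProblem(
        wishlist_name=wishlist.name,
        phase=wishlist.phase,
        context=context,
        grid=structures.grid,
        constraints=constraints,
        objectives=objectives,
        aux_masks=cache,
    )
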