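"""Packaged wishlists (golden-file row enumeration), resolution, serde."""

import numpy as np
import pytest
from pydantic import ValidationError

from lexiplan.errors import StructureError
from lexiplan.phantom import PhantomSpec, default_grid, generate_phantom
from lexiplan.wishlist import (PrescriptionContext, Wishlist, builtin_wishlist,
                               load_wishlist, resolve, save_wishlist)


@pytest.fixture(scope="module")
def ctx():
    return PrescriptionContext()


@pytest.fixture(scope="module")
def structures():
    spec = PhantomSpec(seed=0)
    return generate_phantom(spec, default_grid(spec, 6.0))


# --- golden-file enumeration of the packaged whole-pelvis protocol -------

PHASE1_CONSTRAINTS = [
    ("PTV-P", "MAX", 105, "D_high"),
    ("PTV-P", "MEAN", 101, "D_high"),
    ("PTV-LN - PTV-P+5mm", "MAX", 105, "D_low"),
    ("PTV-LN - PTV-P+5mm", "MEAN", 101, "D_low"),
    ("Left+right femoral head", "MAX", 70, "D_high"),
    ("PTV-LN shell 50 mm", "MAX", 50, "D_high"),
    ("Unspecified tissue", "MAX", 105, "D_high"),
]

# (priority, structure, kind, goal, params); goals as (percent, ref) or value
PHASE1_OBJECTIVES = [
    (1, "PTV-P", "LTCP", 0.65, {"alpha": 0.7, "d_p": (100, "D_high")}),
    (2, "PTV-LN", "LTCP", 0.5, {"alpha": 0.9, "d_p": (100, "D_low")}),
    (3, "PTV-LN shell 5 mm", "MAX", (90, "D_low"), {}),
    (4, "rectum", "EUD", (70, "D_high"), {"k": 12}),
    (4, "rectum", "EUD", (30, "D_high"), {"k": 4}),
    (5, "bladder", "EUD", (30, "D_high"), {"k": 4}),
    (6, "PTV-LN shell 15 mm", "MAX", (60, "D_low"), {}),
    (6, "PTV-LN shell 25 mm", "MAX", (40, "D_low"), {}),
    (7, "bowel_bag", "EUD", (30, "D_high"), {"k": 8}),
    (8, "Skin ring 20 mm", "MAX", (30, "D_high"), {}),
    (9, "rectum", "MEAN", (20, "D_low"), {}),
    (10, "bladder", "MEAN", (20, "D_low"), {}),
    (11, "bowel_bag", "MEAN", (20, "D_low"), {}),
    (12, "Left+right femoral head", "EUD", (10, "D_high"), {"k": 5}),
]

PHASE2_CONSTRAINTS = [
    ("PTV-P", "MAX", 105, "D_p"),
    ("PTV-P", "MEAN", 101, "D_p"),
    ("Left+right femoral head", "MAX", 70, "D_p"),
    ("PTV-P shell 50 mm", "MAX", 50, "D_p"),
    ("Unspecified tissue", "MAX", 105, "D_p"),
]

PHASE2_OBJECTIVES = [
    (1, "PTV-P", "LTCP", 0.5, {"alpha": 0.95, "d_p": (100, "D_p")}),
    (2, "PTV-P shell 5 mm", "MAX", (90, "D_p"), {}),
    (3, "rectum", "EUD", (70, "D_p"), {"k": 16}),
    (4, "bladder", "EUD", (60, "D_p"), {"k": 12}),
    (5, "PTV-P shell 15 mm", "MAX", (50, "D_p"), {}),
    (5, "PTV-P shell 25 mm", "MAX", (30, "D_p"), {}),
    (5, "Skin ring 20 mm", "MAX", (30, "D_p"), {}),
    (6, "rectum", "MEAN", (10, "D_p"), {}),
    (7, "bladder", "MEAN", (10, "D_p"), {}),
    (8, "Left+right femoral head", "EUD", (10, "D_p"), {"k": 5}),
]


@pytest.mark.parametrize("phase,constraints,objectives", [
    (1, PHASE1_CONSTRAINTS, PHASE1_OBJECTIVES),
    (2, PHASE2_CONSTRAINTS, PHASE2_OBJECTIVES),
])
def test_builtin_wishlist_reproduces_every_row(phase, constraints, objectives):
    wl = builtin_wishlist(phase)
    assert len(wl.constraints) == len(constraints)
    for c, (structure, kind, pct, ref) in zip(wl.constraints, constraints):
        assert (c.structure, c.type) == (structure, kind)
        assert (c.limit.percent, c.limit.of) == (pct, ref)
    assert len(wl.objectives) == len(objectives)
    for o, (prio, structure, kind, goal, params) in zip(wl.objectives, objectives):
        assert (o.priority, o.structure, o.cost.kind) == (prio, structure, kind)
        if kind == "LTCP":
            assert o.goal.value == goal
            assert o.cost.alpha == params["alpha"]
            assert (o.cost.d_p.percent, o.cost.d_p.of) == params["d_p"]
        else:
            assert (o.goal.percent, o.goal.of) == goal
            if kind == "EUD":
                assert o.cost.k == params["k"]


def test_phase_counts():
    # phase 1: priorities 1-12, two slots carrying two rows each
    wl1 = builtin_wishlist(1)
    assert sorted({o.priority for o in wl1.objectives}) == list(range(1, 13))
    prios = [o.priority for o in wl1.objectives]
    assert prios.count(4) == 2 and prios.count(6) == 2
    # phase 2: priorities 1-8, priority 5 carrying three rows
    wl2 = builtin_wishlist(2)
    assert sorted({o.priority for o in wl2.objectives}) == list(range(1, 9))
    assert [o.priority for o in wl2.objectives].count(5) == 3


def test_invalid_phase_rejected():
    with pytest.raises(ValueError):
        builtin_wishlist(3)


# --- resolution -----------------------------------------------------------

def test_resolve_percent_to_gy(structures, ctx):
    prob = resolve(builtin_wishlist(1), ctx, structures)
    limits = {(c.structure, c.kind): c.limit_gy for c in prob.constraints}
    assert limits[("PTV-P", "MAX")] == pytest.approx(63.0)           # 1.05 * 60
    assert limits[("PTV-P", "MEAN")] == pytest.approx(60.6)          # 1.01 * 60
    assert limits[("Left+right femoral head", "MAX")] == pytest.approx(42.0)
    assert limits[("PTV-LN - PTV-P+5mm", "MAX")] == pytest.approx(52.5)
    assert limits[("Unspecified tissue", "MAX")] == pytest.approx(63.0)
    goals = {(o.priority, o.structure): o.goal for o in prob.objectives}
    assert goals[(1, "PTV-P")] == 0.65                               # unitless
    assert goals[(3, "PTV-LN shell 5 mm")] == pytest.approx(45.0)    # 0.9 * 50
    assert goals[(12, "Left+right femoral head")] == pytest.approx(6.0)


def test_resolve_phase2_rectum_eud_goal(structures, ctx):
    prob = resolve(builtin_wishlist(2), ctx, structures)
    goals = {(o.priority, o.structure): o.goal for o in prob.objectives}
    assert goals[(3, "rectum")] == pytest.approx(9.1)   # 0.70 * 13 Gy
    ltcp_rows = [o for o in prob.objectives if o.cost.kind == "LTCP"]
    assert ltcp_rows[0].cost.d_p == pytest.approx(13.0)
    assert ltcp_rows[0].cost.alpha == pytest.approx(0.95)


def test_transition_region_disjointness(structures, ctx):
    from lexiplan import geometry
    prob = resolve(builtin_wishlist(1), ctx, structures)
    ring = prob.aux_masks["PTV-LN - PTV-P+5mm"]
    trans = geometry.expand(structures["PTV-P"], 5.0, structures.grid)
    assert not np.any(ring & trans)
    assert np.any(ring)


def test_shells_exclude_targets_and_lie_inside_body(structures, ctx):
    prob = resolve(builtin_wishlist(1), ctx, structures)
    for name, mask in prob.aux_masks.items():
        if "shell" in name or "ring" in name.lower():
            assert not np.any(mask & structures["PTV-LN"]), name
            assert not np.any(mask & ~structures["external"]), name


def test_unspecified_tissue_excludes_everything_named(structures, ctx):
    prob = resolve(builtin_wishlist(1), ctx, structures)
    unspec = prob.aux_masks["Unspecified tissue"]
    assert np.any(unspec)
    for name in structures.names:
        if name != "external":
            assert not np.any(unspec & structures[name]), name
    for name, mask in prob.aux_masks.items():
        if name != "Unspecified tissue":
            assert not np.any(unspec & mask), name


def test_resolve_is_pure(structures, ctx):
    a = resolve(builtin_wishlist(1), ctx, structures)
    b = resolve(builtin_wishlist(1), ctx, structures)
    assert [c.limit_gy for c in a.constraints] == [c.limit_gy for c in b.constraints]
    for oa, ob in zip(a.objectives, b.objectives):
        assert np.array_equal(oa.voxels, ob.voxels)


def test_unresolvable_structure_named_in_error(structures, ctx):
    wl = builtin_wishlist(1).model_copy(deep=True)
    wl.objectives[0].structure = "no_such_organ"
    with pytest.raises(StructureError, match="no_such_organ"):
        resolve(wl, ctx, structures)


# --- (de)serialization ----------------------------------------------------

@pytest.mark.parametrize("phase", [1, 2])
def test_yaml_roundtrip_identity(tmp_path, phase):
    wl = builtin_wishlist(phase)
    path = tmp_path / "wl.yaml"
    save_wishlist(wl, path)
    assert load_wishlist(path) == wl


def test_goal_override_survives_roundtrip(tmp_path):
    wl = builtin_wishlist(1).model_copy(deep=True)
    wl.objectives[0].goal.value = 0.42
    save_wishlist(wl, tmp_path / "wl.yaml")
    assert load_wishlist(tmp_path / "wl.yaml").objectives[0].goal.value == 0.42


def test_zero_priority_rejected():
    data = builtin_wishlist(1).model_dump(exclude_none=True)
    data["objectives"][0]["priority"] = 0
    with pytest.raises(ValidationError, match="priority"):
        Wishlist.model_validate(data)


def test_unknown_cost_kind_rejected():
    data = builtin_wishlist(1).model_dump(exclude_none=True)
    data["objectives"][0]["cost"]["kind"] = "NTCP"
    with pytest.raises(ValidationError):
        Wishlist.model_validate(data)


def test_conflicting_quantity_forms_rejected():
    data = builtin_wishlist(1).model_dump(exclude_none=True)
    data["constraints"][0]["limit"] = {"gy": 63.0, "percent": 105, "of": "D_high"}
    with pytest.raises(ValidationError):
        Wishlist.model_validate(data)
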