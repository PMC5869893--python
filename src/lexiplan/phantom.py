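"""Seeded synthetic pelvis phantoms.

The phantom emulates the anatomy of whole-pelvis prostate radiotherapy
(WPRT): an elliptic body contour, a prostate target (CTV-P) abutting the
rectum, a concave nodal target (CTV-LN) that wraps horseshoe-like around
bladder and bowel, a bowel bag extending a fixed 20 mm cranial of the
nodal target, and lateral femoral heads.  PTVs are the CTVs expanded by
the 5 mm setup margin.  A seed plus a small uniform jitter of organ
centres/radii produces reproducible "patients" for cohort studies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
import yaml

from . import geometry
from .errors import GeometryError
from .grid import StructureSet, VoxelGrid

#: CTV -> PTV setup margin (mm).
SETUP_MARGIN_MM = 5.0
#: Cranial extension of the bowel bag beyond the nodal target (mm).
BOWEL_CRANIAL_EXTENSION_MM = 20.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry parameters (mm) + seed that fully determine a phantom."""

    # body: elliptic cylinder (desk-scale pelvis, ~230 x 190 x 180 mm)
    body_semiaxis_x: float = 115.0
    body_semiaxis_y: float = 95.0
    body_half_length_z: float = 90.0

    # prostate = CTV-P (sphere)
    prostate_center: Tuple[float, float, float] = (0.0, 15.0, -30.0)
    prostate_radius: float = 20.0

    # rectum: cylinder along z, posterior to and abutting the prostate
    rectum_center_xy: Tuple[float, float] = (0.0, 52.0)
    rectum_radius: float = 15.0
    rectum_z_range: Tuple[float, float] = (-70.0, 30.0)

    # bladder: ellipsoid, anterior-superior of the prostate
    bladder_center: Tuple[float, float, float] = (0.0, -20.0, 15.0)
    bladder_semiaxes: Tuple[float, float, float] = (30.0, 28.0, 30.0)

    # bowel bag: elliptic cylinder in the nodal concavity; its cranial
    # extent is derived from the nodal target, not set here
    bowel_center_xy: Tuple[float, float] = (0.0, -8.0)
    bowel_semiaxes_xy: Tuple[float, float] = (36.0, 30.0)
    bowel_z_min: float = 0.0

    # femoral heads (spheres)
    femoral_head_center: Tuple[float, float, float] = (80.0, 10.0, -25.0)
    femoral_head_radius: float = 20.0

    # nodal target CTV-LN: tube swept along an elliptic arc, opening anterior
    nodal_path_center_xy: Tuple[float, float] = (0.0, 8.0)
    nodal_path_semiaxes_xy: Tuple[float, float] = (55.0, 45.0)
    nodal_tube_radius: float = 13.0
    nodal_arc_deg: Tuple[float, float] = (-50.0, 230.0)
    nodal_z_range: Tuple[float, float] = (-20.0, 60.0)
    #: gap kept between the nodal CTV and each OAR (mm)
    nodal_oar_clearance: float = 2.0

    #: amplitude of the uniform anatomy jitter (mm); centres move by
    #: U(-a, a) per axis, radii/semi-axes by U(-a/2, a/2)
    jitter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        radii = [
            self.prostate_radius,
            self.rectum_radius,
            self.femoral_head_radius,
            self.nodal_tube_radius,
            *self.bladder_semiaxes,
            *self.bowel_semiaxes_xy,
        ]
        if any(r <= 0 for r in radii):
            raise ValueError("all organ radii/semi-axes must be > 0")
        if self.jitter_mm < 0 or self.jitter_mm >= min(radii):
            raise ValueError(
                f"jitter amplitude {self.jitter_mm} must be >= 0 and smaller "
                f"than the smallest organ radius {min(radii)}"
            )

    # ------------------------------------------------------------- serde
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)

    def save(self, path):
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PhantomSpec":
        return dataclasses.replace(self, seed=int(seed))


def default_grid(spec: PhantomSpec = None, spacing_mm: float = 4.0) -> VoxelGrid:
    """A grid that symmetrically covers the phantom body plus a small margin."""
    spec = spec or PhantomSpec()
    pad = 2 * spacing_mm + spec.jitter_mm
    extent = (
        2 * (spec.body_semiaxis_x + pad),
        2 * (spec.body_semiaxis_y + pad),
        2 * (spec.body_half_length_z + pad),
    )
    return VoxelGrid.centered(extent, spacing_mm)


def _jittered(spec: PhantomSpec):
    """Draw the seeded anatomy perturbation; returns a plain namespace dict."""
    rng = np.random.default_rng(spec.seed)
    a = spec.jitter_mm

    def c(vals, n):  # jitter a centre-like tuple
        return tuple(np.asarray(vals, float) + rng.uniform(-a, a, n))

    def r(vals):  # jitter a radius or semi-axis tuple
        arr = np.atleast_1d(np.asarray(vals, float))
        out = arr + rng.uniform(-a / 2, a / 2, arr.size)
        return float(out[0]) if np.isscalar(vals) or arr.size == 1 else tuple(out)

    p = {}
    p["prostate_center"] = c(spec.prostate_center, 3)
    p["prostate_radius"] = r(spec.prostate_radius)
    p["rectum_center_xy"] = c(spec.rectum_center_xy, 2)
    p["rectum_radius"] = r(spec.rectum_radius)
    p["bladder_center"] = c(spec.bladder_center, 3)
    p["bladder_semiaxes"] = r(spec.bladder_semiaxes)
    p["bowel_center_xy"] = c(spec.bowel_center_xy, 2)
    p["bowel_semiaxes_xy"] = r(spec.bowel_semiaxes_xy)
    # femoral heads jittered independently left/right
    fx, fy, fz = spec.femoral_head_center
    p["fem_left_center"] = c((-fx, fy, fz), 3)
    p["fem_right_center"] = c((fx, fy, fz), 3)
    p["fem_left_radius"] = r(spec.femoral_head_radius)
    p["fem_right_radius"] = r(spec.femoral_head_radius)
    p["nodal_path_center_xy"] = c(spec.nodal_path_center_xy, 2)
    p["nodal_path_semiaxes_xy"] = r(spec.nodal_path_semiaxes_xy)
    p["nodal_tube_radius"] = r(spec.nodal_tube_radius)
    return p


def _sphere(grid, center, radius):
    x, y, z = grid.coordinate_arrays()
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2


def _ellipsoid(grid, center, semi):
    x, y, z = grid.coordinate_arrays()
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
        <= 1.0
    )


def _zslab(grid, z_min, z_max):
    _, _, z = grid.coordinate_arrays()
    return (z >= z_min) & (z <= z_max)


def _elliptic_cylinder(grid, center_xy, semi_xy, z_min, z_max):
    x, y, _ = grid.coordinate_arrays()
    in_xy = ((x - center_xy[0]) / semi_xy[0]) ** 2 + ((y - center_xy[1]) / semi_xy[1]) ** 2 <= 1.0
    return in_xy & _zslab(grid, z_min, z_max)


def _nodal_ring(grid, center_xy, semi_xy, tube_radius, arc_deg, z_range):
    """Tube of given radius swept along an elliptic arc (2D distance test)."""
    theta = np.radians(np.linspace(arc_deg[0], arc_deg[1], 512))
    px = center_xy[0] + semi_xy[0] * np.cos(theta)
    py = center_xy[1] + semi_xy[1] * np.sin(theta)
    xs = grid.axis_coords(0)[:, None]
    ys = grid.axis_coords(1)[None, :]
    d2 = np.full((grid.dims[0], grid.dims[1]), np.inf)
    for k in range(0, theta.size, 64):
        chunk_x = px[k : k + 64][None, None, :]
        chunk_y = py[k : k + 64][None, None, :]
        d2 = np.minimum(d2, ((xs[..., None] - chunk_x) ** 2 + (ys[..., None] - chunk_y) ** 2).min(axis=2))
    in_xy = d2 <= tube_radius**2
    return in_xy[:, :, None] & _zslab(grid, z_range[0], z_range[1])


def generate_phantom(spec: PhantomSpec, grid: VoxelGrid = None) -> StructureSet:
    """Build the full WPRT structure set; identical spec+seed give identical masks."""
    grid = grid or default_grid(spec)
    p = _jittered(spec)

    x, y, z = grid.coordinate_arrays()
    external = (
        (x / spec.body_semiaxis_x) ** 2 + (y / spec.body_semiaxis_y) ** 2 <= 1.0
    ) & _zslab(grid, -spec.body_half_length_z, spec.body_half_length_z)
    if not external.any():
        raise GeometryError("grid does not contain the body contour")

    ctv_p = _sphere(grid, p["prostate_center"], p["prostate_radius"])
    rectum = _elliptic_cylinder(
        grid,
        p["rectum_center_xy"],
        (p["rectum_radius"], p["rectum_radius"]),
        spec.rectum_z_range[0],
        spec.rectum_z_range[1],
    )
    bladder = _ellipsoid(grid, p["bladder_center"], p["bladder_semiaxes"])
    fem_l = _sphere(grid, p["fem_left_center"], p["fem_left_radius"])
    fem_r = _sphere(grid, p["fem_right_center"], p["fem_right_radius"])

    ring = _nodal_ring(
        grid,
        p["nodal_path_center_xy"],
        p["nodal_path_semiaxes_xy"],
        p["nodal_tube_radius"],
        spec.nodal_arc_deg,
        spec.nodal_z_range,
    )
    # keep a clearance between the nodal CTV and each OAR so CTV voxels are
    # never simultaneously organ voxels (PTV margins may still overlap OARs)
    gap = spec.nodal_oar_clearance
    for oar in (rectum, bladder, fem_l, fem_r):
        ring &= ~geometry.expand(oar, gap, grid)
    ctv_ln = ring | ctv_p

    # the bowel bag fills the anterior concavity and is delineated up to
    # a fixed 20 mm cranial of the nodal target's cranial extent
    z_coords = grid.axis_coords(2)
    ln_top = z_coords[np.nonzero(ctv_ln.any(axis=(0, 1)))[0].max()]
    bowel = _elliptic_cylinder(
        grid,
        p["bowel_center_xy"],
        p["bowel_semiaxes_xy"],
        spec.bowel_z_min,
        ln_top + BOWEL_CRANIAL_EXTENSION_MM,
    )
    bowel &= ~geometry.expand(ctv_ln, gap, grid)

    organs = {
        "CTV-P": ctv_p,
        "CTV-LN": ctv_ln,
        "rectum": rectum,
        "bladder": bladder,
        "bowel_bag": bowel,
        "femoral_head_left": fem_l,
        "femoral_head_right": fem_r,
    }
    for name, mask in organs.items():
        if not mask.any():
            raise GeometryError(f"organ {name!r} is empty on this grid")
        if np.any(mask & ~external):
            raise GeometryError(f"organ {name!r} extends outside the body contour")

    ptv_p = geometry.expand(ctv_p, SETUP_MARGIN_MM, grid) & external
    ptv_ln = geometry.expand(ctv_ln, SETUP_MARGIN_MM, grid) & external

    ss = StructureSet(
        grid,
        {"external": external, **organs, "PTV-P": ptv_p, "PTV-LN": ptv_ln},
    )
    ss.validate_wprt()
    return ss


def cohort(spec: PhantomSpec, n: int):
    """Specs for ``n`` jittered cases, seeds derived deterministically."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    return [spec.with_seed(int(s)) for s in seeds]
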