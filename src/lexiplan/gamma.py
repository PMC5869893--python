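"""3D gamma-index comparison of two dose distributions.

The gamma index at a reference voxel r combines the local dose
difference and the distance-to-agreement into one pass/fail number:

    gamma(r) = min over r' of sqrt( (|r - r'| / dta)^2
                + ((D_eval(r') - D_ref(r)) / (pct/100 * D_ref(r)))^2 )

with *local* dose normalization (the tolerance scales with the
reference dose at r).  A voxel passes when gamma <= 1; the gamma pass
rate (GPR) is the percentage of evaluated voxels passing.  Voxels whose
reference dose falls below a low-dose cutoff (10% of the reference
maximum by default) are excluded from the statistic, as is standard QA
practice.  The clinical criterion used here is 3% / 3 mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError
from .grid import VoxelGrid


@dataclass
class GammaResult:
    gamma_map: np.ndarray        # NaN outside the evaluated region
    pass_rate: float             # % of evaluated voxels with gamma <= 1
    dose_pct: float
    dist_mm: float
    cutoff_pct: float
    n_evaluated: int

    def summary(self) -> dict:
        return {
            "gamma_pass_rate_pct": self.pass_rate,
            "criteria": f"{self.dose_pct:g}%/{self.dist_mm:g}mm",
            "low_dose_cutoff_pct": self.cutoff_pct,
            "n_evaluated": self.n_evaluated,
            "gamma_mean": float(np.nanmean(self.gamma_map)),
        }


def _search_offsets(dist_mm: float, spacing, search_factor: float,
                    step_fraction: float):
    """Displacement lattice (mm) out to ``search_factor * dist_mm``.

    Half-voxel steps give sub-voxel distance-to-agreement resolution; a
    gamma whose spatial term alone exceeds ``search_factor`` cannot pass,
    so the search radius is capped there.
    """
    step = float(min(spacing)) * step_fraction
    radius = search_factor * dist_mm
    n = int(np.floor(radius / step))
    axis = step * np.arange(-n, n + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    offsets = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    r = np.linalg.norm(offsets, axis=1)
    offsets = offsets[r <= radius]
    # visit near offsets first so the running minimum converges quickly
    return offsets[np.argsort(np.linalg.norm(offsets, axis=1))]


def gamma(
    ref_dose: np.ndarray,
    eval_dose: np.ndarray,
    grid: VoxelGrid,
    dose_pct: float = 3.0,
    dist_mm: float = 3.0,
    cutoff_pct: float = 10.0,
    search_factor: float = 3.0,
    step_fraction: float = 0.5,
) -> GammaResult:
    """Gamma analysis with local dose normalization (default 3%/3 mm)."""
    ref = np.asarray(ref_dose, float)
    ev = np.asarray(eval_dose, float)
    if ref.shape != ev.shape or ref.shape != grid.shape:
        raise GridMismatchError(
            f"dose grids differ: {ref.shape} vs {ev.shape} (grid {grid.shape})")
    if dose_pct <= 0 or dist_mm <= 0:
        raise ValueError("criteria must be positive")

    ref_max = ref.max()
    evaluate = ref > (cutoff_pct / 100.0) * ref_max
    if not evaluate.any():
        raise ValueError("all reference voxels fall below the low-dose cutoff")

    flat_idx = np.flatnonzero(evaluate)
    ref_vals = ref.ravel()[flat_idx]
    tol_dose = (dose_pct / 100.0) * ref_vals
    base = np.array(np.unravel_index(flat_idx, grid.shape), float).T  # (n, 3)
    spacing = np.asarray(grid.spacing)

    gamma2 = np.full(flat_idx.size, np.inf)
    for off in _search_offsets(dist_mm, grid.spacing, search_factor, step_fraction):
        space2 = float(np.sum((off / dist_mm) ** 2))
        if space2 > gamma2.max():
            continue  # no voxel can improve at this or any farther offset
        coords = (base + off / spacing).T
        shifted = ndimage.map_coordinates(ev, coords, order=1, mode="nearest")
        g2 = space2 + ((shifted - ref_vals) / tol_dose) ** 2
        np.minimum(gamma2, g2, out=gamma2)

    gmap = np.full(grid.shape, np.nan).ravel()
    gmap[flat_idx] = np.sqrt(gamma2)
    gmap = gmap.reshape(grid.shape)
    pass_rate = float(100.0 * np.mean(np.sqrt(gamma2) <= 1.0))
    return GammaResult(gmap, pass_rate, dose_pct, dist_mm, cutoff_pct, flat_idx.size)


def resample(dose: np.ndarray, from_grid: VoxelGrid, to_grid: VoxelGrid,
             fill: float = np.nan) -> np.ndarray:
    """Trilinear resampling of a dose grid onto another grid.

    Voxels of ``to_grid`` outside the extent of ``from_grid`` are set to
    ``fill`` (NaN marks them excluded).  Completely disjoint extents are
    an error.
    """
    dose = np.asarray(dose, float)
    if dose.shape != from_grid.shape:
        raise GridMismatchError("dose does not match its source grid")
    xt, yt, zt = np.meshgrid(
        to_grid.axis_coords(0), to_grid.axis_coords(1), to_grid.axis_coords(2),
        indexing="ij",
    )
    pts = np.stack([xt.ravel(), yt.ravel(), zt.ravel()], axis=1)
    idx = from_grid.world_to_index(pts)
    upper = np.asarray(from_grid.dims) - 1
    inside = np.all((idx >= 0) & (idx <= upper), axis=1)
    if not inside.any():
        raise GridMismatchError("grids have disjoint extents; cannot resample")
    out = np.full(idx.shape[0], fill)
    out[inside] = ndimage.map_coordinates(dose, idx[inside].T, order=1, mode="nearest")
    return out.reshape(to_grid.shape)
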