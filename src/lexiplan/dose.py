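"""Equi-angular beam geometry and the linear dose-influence matrix.

The delivery is approximated the way the pre-optimizer approaches a full
arc: ``n`` static, equi-angularly spaced coplanar beams (20 by default),
each decomposed into a rectangular grid of beamlets.  The physics is a
deliberately simple water-equivalent surrogate — a divergent ray per
beamlet with exponential depth attenuation exp(-mu * depth) and a
Gaussian lateral spread of width sigma — linear in the beamlet weights,
which is all the fluence optimization requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import sparse

from .errors import GridMismatchError
from .grid import VoxelGrid

#: Default isocentre dose for unit uniform fluence from all beams (Gy).
DEFAULT_CALIBRATION_GY = 2.0


@dataclass(frozen=True)
class PhysicsParams:
    """Parameters of the water-equivalent pencil-kernel surrogate."""

    mu_per_cm: float = 0.04        # linear attenuation coefficient
    sigma_mm: float = 5.0          # lateral Gaussian width
    calibration_gy: Optional[float] = DEFAULT_CALIBRATION_GY
    # entries below this fraction of each beamlet's peak are dropped
    sparsity_cutoff: float = 1e-3
    inverse_square: bool = False   # off by default: flat-depth fluence
    ray_step_mm: float = 2.0       # marching step when locating the skin entry

    def __post_init__(self):
        if self.mu_per_cm < 0 or self.sigma_mm <= 0:
            raise ValueError("mu must be >= 0 and sigma > 0")


@dataclass(frozen=True)
class BeamSet:
    """Gantry angles plus a common beamlet grid in the isocentre plane."""

    gantry_angles_deg: Tuple[float, ...]
    isocenter_mm: Tuple[float, float, float]
    n_rows: int                    # beamlet rows (along z)
    n_cols: int                    # beamlet columns (in-plane lateral)
    beamlet_size_mm: float = 10.0
    sad_mm: float = 1000.0

    def __post_init__(self):
        if len(self.gantry_angles_deg) < 1:
            raise ValueError("at least one beam is required")
        if any(not (0 <= a < 360) for a in self.gantry_angles_deg):
            raise ValueError("gantry angles must lie in [0, 360)")
        if self.beamlet_size_mm <= 0:
            raise ValueError("beamlet size must be > 0")

    @property
    def n_beams(self) -> int:
        return len(self.gantry_angles_deg)

    @property
    def beamlets_per_beam(self) -> int:
        return self.n_rows * self.n_cols

    def beam_axes(self, angle_deg: float):
        """Unit vectors (direction u, in-plane lateral v, longitudinal w).

        Gantry 0 deg enters anteriorly (travels toward +y); rotation is in
        the axial (x, y) plane.
        """
        t = np.radians(angle_deg)
        u = np.array([np.sin(t), np.cos(t), 0.0])
        v = np.array([np.cos(t), -np.sin(t), 0.0])
        w = np.array([0.0, 0.0, 1.0])
        return u, v, w

    def beamlet_offsets(self):
        """In-plane (a along v, b along z) centre offsets, shape (n, 2)."""
        s = self.beamlet_size_mm
        a = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * s
        b = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * s
        A, B = np.meshgrid(a, b, indexing="ij")  # cols-major: (col, row)
        return np.stack([A.ravel(), B.ravel()], axis=1)


def make_beams(
    n_beams: int,
    isocenter: Optional[Tuple[float, float, float]] = None,
    beamlet_size_mm: float = 10.0,
    target_mask: Optional[np.ndarray] = None,
    grid: Optional[VoxelGrid] = None,
    aperture_margin_mm: float = 8.0,
    sad_mm: float = 1000.0,
) -> BeamSet:
    """Equi-angular coplanar beam set; angles = k * 360/n.

    The isocentre defaults to the centroid of ``target_mask`` (the phase
    target), matching the clinical rule of placing it at the centre of
    the PTV being treated.  The beamlet aperture is sized to cover the
    target's projection from every gantry angle plus a margin.
    """
    if n_beams < 1:
        raise ValueError(f"n_beams must be >= 1, got {n_beams}")
    angles = tuple((360.0 * k) / n_beams for k in range(n_beams))

    if target_mask is not None:
        if grid is None:
            raise ValueError("grid is required when sizing from a target mask")
        pts = grid.points(np.flatnonzero(target_mask))
        centroid = pts.mean(axis=0)
        if isocenter is None:
            isocenter = tuple(centroid)
        rel = pts - np.asarray(isocenter)
        r_xy = float(np.hypot(rel[:, 0], rel[:, 1]).max()) + aperture_margin_mm
        r_z = float(np.abs(rel[:, 2]).max()) + aperture_margin_mm
        n_cols = max(1, int(np.ceil(2 * r_xy / beamlet_size_mm)))
        n_rows = max(1, int(np.ceil(2 * r_z / beamlet_size_mm)))
    else:
        if isocenter is None:
            raise ValueError("either an isocenter or a target mask is required")
        n_cols = n_rows = 1

    return BeamSet(
        gantry_angles_deg=angles,
        isocenter_mm=tuple(float(c) for c in isocenter),
        n_rows=n_rows,
        n_cols=n_cols,
        beamlet_size_mm=beamlet_size_mm,
        sad_mm=sad_mm,
    )


@dataclass
class DoseInfluenceMatrix:
    """Sparse linear map from beamlet weights to dose in body voxels.

    ``matrix`` has shape (n_body_voxels, n_beamlets); entries are Gy per
    unit beamlet weight.  ``voxel_index`` holds the flat grid index of
    each row; ``beamlet_table`` records (beam, row, col) per column.
    """

    matrix: sparse.csr_matrix
    voxel_index: np.ndarray
    beamlet_table: np.ndarray  # structured: beam, row, col, offset_a, offset_b
    grid: VoxelGrid
    beams: BeamSet
    physics: PhysicsParams
    zero_columns: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    def rows_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Row indices of this matrix covering a structure mask."""
        inv = np.full(self.grid.n_voxels, -1, dtype=np.int64)
        inv[self.voxel_index] = np.arange(self.voxel_index.size)
        rows = inv[np.flatnonzero(mask)]
        return rows[rows >= 0]

    def dose_from_fluence(self, weights: np.ndarray) -> np.ndarray:
        """Dose grid d = D x (Gy), zero outside the body."""
        w = np.asarray(weights, float).ravel()
        if w.size != self.n_beamlets:
            raise ValueError(f"expected {self.n_beamlets} weights, got {w.size}")
        if np.any(w < 0):
            raise ValueError("fluence weights must be nonnegative")
        flat = np.zeros(self.grid.n_voxels)
        flat[self.voxel_index] = self.matrix @ w.astype(self.matrix.dtype, copy=False)
        return flat.reshape(self.grid.shape)

    # ------------------------------------------------------------- serde
    def save(self, path):
        """Sparse container: .npz payload plus a JSON sidecar header."""
        path = Path(path)
        sparse.save_npz(path.with_suffix(".npz"), self.matrix.tocoo())
        np.savez(
            path.with_suffix(".tables.npz"),
            voxel_index=self.voxel_index,
            beamlet_table=self.beamlet_table,
            zero_columns=self.zero_columns,
        )
        header = {
            "grid": {"dims": list(self.grid.dims), "spacing": list(self.grid.spacing), "origin": list(self.grid.origin)},
            "beams": {
                "gantry_angles_deg": list(self.beams.gantry_angles_deg),
                "isocenter_mm": list(self.beams.isocenter_mm),
                "n_rows": self.beams.n_rows,
                "n_cols": self.beams.n_cols,
                "beamlet_size_mm": self.beams.beamlet_size_mm,
                "sad_mm": self.beams.sad_mm,
            },
            "physics": {
                "mu_per_cm": self.physics.mu_per_cm,
                "sigma_mm": self.physics.sigma_mm,
                "calibration_gy": self.physics.calibration_gy,
                "sparsity_cutoff": self.physics.sparsity_cutoff,
                "inverse_square": self.physics.inverse_square,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path) -> "DoseInfluenceMatrix":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        g = header["grid"]
        grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
        b = header["beams"]
        beams = BeamSet(tuple(b["gantry_angles_deg"]), tuple(b["isocenter_mm"]), b["n_rows"], b["n_cols"], b["beamlet_size_mm"], b["sad_mm"])
        tables = np.load(path.with_suffix(".tables.npz"))
        return cls(
            matrix=sparse.load_npz(path.with_suffix(".npz")).tocsr(),
            voxel_index=tables["voxel_index"],
            beamlet_table=tables["beamlet_table"],
            grid=grid,
            beams=beams,
            physics=PhysicsParams(**header["physics"]),
            zero_columns=tables["zero_columns"],
        )


def dose_from_fluence(dij: DoseInfluenceMatrix, weights: np.ndarray) -> np.ndarray:
    return dij.dose_from_fluence(weights)


def _entry_depth(source, direction, external, grid, step_mm, sad_mm):
    """Ray-march from the source to find the skin-entry distance t0 (mm)."""
    half_diag = float(np.linalg.norm(
        [grid.dims[a] * grid.spacing[a] for a in range(3)]))
    ts = np.arange(max(0.0, sad_mm - half_diag), sad_mm + half_diag, step_mm)
    pts = source[None, :] + ts[:, None] * direction[None, :]
    idx = np.rint(grid.world_to_index(pts)).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(grid.dims)), axis=1)
    inside = np.zeros(ts.size, bool)
    inside[ok] = external[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    hits = np.nonzero(inside)[0]
    return None if hits.size == 0 else float(ts[hits[0]])


def compute_dij(
    grid: VoxelGrid,
    external: np.ndarray,
    beams: BeamSet,
    physics: PhysicsParams = PhysicsParams(),
    prune_mask: Optional[np.ndarray] = None,
    prune_margin_mm: float = 5.0,
    dtype=np.float32,
) -> DoseInfluenceMatrix:
    """Trace every beamlet's divergent ray through the body.

    Dose per unit weight at a voxel at depth ``t`` along the ray and
    lateral distance ``r`` from it:  ``C * exp(-mu*t) * exp(-r^2/(2 sigma^2))``
    (optionally times an inverse-square factor), zero outside ``external``.
    If ``prune_mask`` is given, beamlets whose ray never passes within
    ``prune_margin_mm`` (plus half a beamlet) of the mask are omitted.
    ``calibration_gy`` rescales the matrix so unit weight on every kept
    beamlet yields that dose at the isocentre.
    """
    external = np.asarray(external, bool)
    if external.shape != grid.shape:
        raise GridMismatchError("external mask does not match grid")
    if not external.any():
        raise ValueError("external mask is empty")

    voxel_index = np.flatnonzero(external)
    pts = grid.points(voxel_index)  # (N, 3)
    iso = np.asarray(beams.isocenter_mm)
    rel = pts - iso
    sigma = physics.sigma_mm
    # lateral reach implied by the sparsity cutoff
    r_cut = sigma * np.sqrt(2.0 * np.log(1.0 / max(physics.sparsity_cutoff, 1e-12)))

    prune_pts = None
    if prune_mask is not None:
        prune_pts = grid.points(np.flatnonzero(prune_mask)) - iso

    offsets = beams.beamlet_offsets()
    rows_all, cols_all, vals_all = [], [], []
    col_meta = []
    zero_cols = []
    col = 0
    for beam_idx, angle in enumerate(beams.gantry_angles_deg):
        u, v, w = beams.beam_axes(angle)
        source = iso - beams.sad_mm * u
        A = rel @ v
        B = rel @ w
        T = rel @ u
        div = 1.0 + T / beams.sad_mm  # lateral magnification with depth
        if prune_pts is not None:
            pa = prune_pts @ v
            pb = prune_pts @ w
        half = beams.beamlet_size_mm / 2.0
        for local, (a, b) in enumerate(offsets):
            if prune_pts is not None:
                keep = np.any(
                    (np.abs(pa - a) <= half + prune_margin_mm)
                    & (np.abs(pb - b) <= half + prune_margin_mm)
                )
                if not keep:
                    continue
            # coarse candidate cull (parallel approximation + divergence slack)
            slack = r_cut + 0.25 * max(abs(a), abs(b)) + 2.0
            cand = np.nonzero((np.abs(A - a) <= slack) & (np.abs(B - b) <= slack))[0]
            row_idx = np.array([], int)
            dose = np.array([])
            if cand.size:
                p_center = iso + a * v + b * w
                d_vec = p_center - source
                d_vec = d_vec / np.linalg.norm(d_vec)
                t0 = _entry_depth(source, d_vec, external, grid,
                                  physics.ray_step_mm, beams.sad_mm)
                if t0 is not None:
                    rel_s = pts[cand] - source
                    t = rel_s @ d_vec
                    r2 = np.maximum(np.einsum("ij,ij->i", rel_s, rel_s) - t * t, 0.0)
                    depth = t - t0
                    ok = (depth >= 0) & (r2 <= r_cut**2)
                    if ok.any():
                        dose = np.exp(-physics.mu_per_cm * depth[ok] / 10.0) * np.exp(
                            -r2[ok] / (2.0 * sigma**2)
                        )
                        if physics.inverse_square:
                            dose *= (beams.sad_mm / t[ok]) ** 2
                        row_idx = cand[ok]
                        keep_e = dose >= physics.sparsity_cutoff * dose.max()
                        row_idx, dose = row_idx[keep_e], dose[keep_e]
            if row_idx.size == 0:
                zero_cols.append(col)
            rows_all.append(row_idx)
            cols_all.append(np.full(row_idx.size, col, dtype=np.int64))
            vals_all.append(dose)
            col_meta.append((beam_idx, a, b))
            col += 1

    beamlet_table = np.zeros(
        col,
        dtype=[("beam", "i4"), ("row", "i4"), ("col", "i4"), ("offset_a", "f8"), ("offset_b", "f8")],
    )
    for i, (bi, a, b) in enumerate(col_meta):
        beamlet_table[i] = (bi, int(round((b / beams.beamlet_size_mm) + (beams.n_rows - 1) / 2)), int(round((a / beams.beamlet_size_mm) + (beams.n_cols - 1) / 2)), a, b)

    D = sparse.coo_matrix(
        (np.concatenate(vals_all) if vals_all else np.zeros(0),
         (np.concatenate(rows_all) if rows_all else np.zeros(0, int),
          np.concatenate(cols_all) if cols_all else np.zeros(0, int))),
        shape=(voxel_index.size, col),
    ).tocsr()

    if physics.calibration_gy is not None and D.nnz:
        iso_row = int(np.argmin(np.einsum("ij,ij->i", rel, rel)))
        unit = float(D[iso_row].sum())
        if unit > 0:
            D = D * (physics.calibration_gy / unit)

    return DoseInfluenceMatrix(
        matrix=D.astype(dtype),
        voxel_index=voxel_index,
        beamlet_table=beamlet_table,
        grid=grid,
        beams=beams,
        physics=physics,
        zero_columns=np.asarray(zero_cols, int),
    )
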