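"""Voxel grids, structure sets, and their NIfTI serialization.

Conventions used throughout the package: arrays are indexed ``[ix, iy, iz]``
with axes x = patient left-right, y = anterior-posterior (+y posterior),
z = inferior-superior (+z cranial); all lengths are millimetres; world
coordinates refer to voxel centres, ``world = origin + index * spacing``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, StructureError

#: Structure names every whole-pelvis planning problem must provide.
REQUIRED_STRUCTURES = (
    "external",
    "CTV-P",
    "CTV-LN",
    "PTV-P",
    "PTV-LN",
    "rectum",
    "bladder",
    "bowel_bag",
    "femoral_head_left",
    "femoral_head_right",
)


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D grid: the common substrate for masks and dose arrays."""

    dims: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on each axis, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @classmethod
    def centered(cls, extent_mm, spacing_mm) -> "VoxelGrid":
        """Grid whose voxel centres symmetrically cover ``[-e/2, e/2]`` per axis."""
        spacing = np.broadcast_to(np.asarray(spacing_mm, float), (3,))
        dims = np.maximum(1, np.ceil(np.asarray(extent_mm, float) / spacing).astype(int))
        # odd dims keep a voxel centre exactly at the world origin
        dims += 1 - dims % 2
        origin = -(dims - 1) / 2.0 * spacing
        return cls(tuple(dims), tuple(spacing), tuple(origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def coordinate_arrays(self):
        """Broadcastable world-coordinate arrays (X, Y, Z) of voxel centres."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def points(self, flat_indices: np.ndarray) -> np.ndarray:
        """World coordinates, shape (n, 3), of flat voxel indices."""
        idx = np.unravel_index(np.asarray(flat_indices), self.dims)
        return np.stack(
            [self.origin[a] + self.spacing[a] * idx[a] for a in range(3)], axis=-1
        ).astype(float)

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world points, shape (n, 3)."""
        p = np.atleast_2d(np.asarray(points_mm, float))
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def require_same(self, other: "VoxelGrid"):
        if not self.same_geometry(other):
            raise GridMismatchError(f"grid mismatch: {self} vs {other}")


def _check_mask(grid: VoxelGrid, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != grid.shape:
        raise GridMismatchError(
            f"mask shape {mask.shape} does not match grid dims {grid.shape}"
        )
    return mask.astype(bool)


@dataclass
class StructureSet:
    """Named binary masks sharing one :class:`VoxelGrid`."""

    grid: VoxelGrid
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.masks = {name: _check_mask(self.grid, m) for name, m in self.masks.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.masks[name]
        except KeyError:
            raise StructureError(
                f"structure {name!r} not present; available: {sorted(self.masks)}"
            ) from None

    def __setitem__(self, name: str, mask: np.ndarray):
        self.masks[name] = _check_mask(self.grid, mask)

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    @property
    def names(self):
        return list(self.masks)

    def volume_ml(self, name: str) -> float:
        return float(self[name].sum()) * self.grid.voxel_volume_ml

    def validate_wprt(self):
        """Check the nesting/required-name invariants of a pelvis structure set."""
        for name in REQUIRED_STRUCTURES:
            if name not in self.masks:
                raise StructureError(f"required structure {name!r} is missing")
            if not self.masks[name].any():
                raise StructureError(f"required structure {name!r} is empty")
        ext = self.masks["external"]
        for name, mask in self.masks.items():
            if np.any(mask & ~ext):
                raise StructureError(f"structure {name!r} extends outside 'external'")
        for inner, outer in (("CTV-P", "CTV-LN"), ("PTV-P", "PTV-LN")):
            if np.any(self.masks[inner] & ~self.masks[outer]):
                raise StructureError(f"{inner!r} is not contained in {outer!r}")

    # ------------------------------------------------------------------ I/O

    def save(self, directory) -> Path:
        """Write one NIfTI file per structure plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "grid": {
                "dims": list(self.grid.dims),
                "spacing": list(self.grid.spacing),
                "origin": list(self.grid.origin),
            },
            "structures": {},
        }
        for name, mask in self.masks.items():
            fname = name.replace("/", "_") + ".nii.gz"
            save_dose_nifti(mask.astype(np.uint8), self.grid, directory / fname)
            manifest["structures"][name] = fname
        path = directory / "structures.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, directory) -> "StructureSet":
        directory = Path(directory)
        manifest = json.loads((directory / "structures.json").read_text())
        g = manifest["grid"]
        grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
        masks = {}
        for name, fname in manifest["structures"].items():
            arr, fgrid = load_dose_nifti(directory / fname)
            grid.require_same(fgrid)
            masks[name] = arr > 0.5
        return cls(grid, masks)


def save_dose_nifti(array: np.ndarray, grid: VoxelGrid, path):
    """Write a 3D array (dose in Gy, or a mask) as NIfTI with the grid affine."""
    array = np.asarray(array)
    if array.shape != grid.shape:
        raise GridMismatchError(
            f"array shape {array.shape} does not match grid dims {grid.shape}"
        )
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32 if array.dtype.kind == "f" else array.dtype), grid.affine)
    nib.save(img, str(path))


def load_dose_nifti(path):
    """Read a NIfTI file written by :func:`save_dose_nifti`; returns (array, grid)."""
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    data = np.asarray(img.dataobj)
    grid = VoxelGrid(tuple(int(d) for d in data.shape), spacing, origin)
    return data, grid
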