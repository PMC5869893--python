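"""Structure-geometry operators: margin expansion, shells, rings, booleans.

All distance-based operators use the exact Euclidean distance transform on
voxel centres (``scipy.ndimage.distance_transform_edt`` with the grid
spacing as sampling), so a voxel belongs to ``expand(m, r)`` iff the
distance from its centre to the nearest voxel centre of ``m`` is <= r.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import GridMismatchError
from .grid import VoxelGrid

log = logging.getLogger(__name__)


def _dist_to_mask(mask: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Distance (mm) from every voxel centre to the nearest voxel of ``mask``.

    Zero inside the mask; +inf everywhere if the mask is empty.
    """
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask, sampling=grid.spacing)


def expand(mask: np.ndarray, margin_mm: float, grid: VoxelGrid) -> np.ndarray:
    """Isotropic margin expansion, e.g. the 5 mm CTV-to-PTV setup margin.

    Returns every voxel whose Euclidean distance to ``mask`` is <= margin_mm.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    mask = np.asarray(mask, bool)
    if margin_mm == 0 or not mask.any():
        return mask.copy()
    return _dist_to_mask(mask, grid) <= margin_mm


def shell(
    mask: np.ndarray,
    distance_mm: float,
    grid: VoxelGrid,
    external: np.ndarray,
    thickness_mm: float = 5.0,
) -> np.ndarray:
    """A band of tissue at a stand-off distance around a target.

    Voxels outside ``mask``, inside ``external``, whose distance to ``mask``
    lies in ``(distance_mm, distance_mm + thickness_mm]``.  Used for the
    dose fall-off objectives ("shell 5/15/25/50 mm").  An empty result is
    returned as an empty mask with a logged warning (the corresponding
    wishlist row is dropped downstream).
    """
    if distance_mm < 0:
        raise ValueError(f"shell distance must be >= 0, got {distance_mm}")
    if thickness_mm <= 0:
        raise ValueError(f"shell thickness must be > 0, got {thickness_mm}")
    mask = np.asarray(mask, bool)
    d = _dist_to_mask(mask, grid)
    out = (~mask) & np.asarray(external, bool) & (d > distance_mm) & (d <= distance_mm + thickness_mm)
    if not out.any():
        log.warning(
            "shell at %.1f mm (thickness %.1f mm) is empty inside the body", distance_mm, thickness_mm
        )
    return out


def expansion_beyond(
    mask: np.ndarray, distance_mm: float, grid: VoxelGrid, external: np.ndarray
) -> np.ndarray:
    """All body tissue farther than ``distance_mm`` from the target.

    The full-expansion alternative to the banded :func:`shell`; selectable
    through the wishlist auxiliary-structure recipe.
    """
    mask = np.asarray(mask, bool)
    d = _dist_to_mask(mask, grid)
    return (~mask) & np.asarray(external, bool) & (d > distance_mm)


def inner_ring(external: np.ndarray, depth_mm: float, grid: VoxelGrid) -> np.ndarray:
    """The skin ring: tissue within ``depth_mm`` of the body surface.

    Distance is measured to the nearest voxel centre outside ``external``.
    A depth larger than the body half-width simply returns all of external.
    """
    if depth_mm <= 0:
        raise ValueError(f"ring depth must be > 0, got {depth_mm}")
    external = np.asarray(external, bool)
    # pad so the body surface is seen even if external touches the grid edge
    padded = np.pad(external, 1)
    d = ndimage.distance_transform_edt(padded, sampling=grid.spacing)[1:-1, 1:-1, 1:-1]
    return external & (d <= depth_mm)


def subtract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & ~b


def union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise GridMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a | b


def unspecified_tissue(external: np.ndarray, structures) -> np.ndarray:
    """Body tissue not claimed by any named target, OAR or auxiliary.

    ``structures`` is an iterable of masks (everything except ``external``
    itself).  The wishlists put a hard max-dose limit on this remainder.
    """
    external = np.asarray(external, bool)
    out = external.copy()
    for m in structures:
        m = np.asarray(m, bool)
        if m.shape != external.shape:
            raise GridMismatchError(f"mask shapes differ: {m.shape} vs {external.shape}")
        out &= ~m
    return out
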