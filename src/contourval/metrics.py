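"""Overlap and surface-distance metrics between binary masks.

Two metrics drive the variability analyses:

* **DSC** (Dice similarity coefficient): ``2|A ∩ B| / (|A| + |B|)``, a
  volume-overlap score in [0, 1].  DSC depends on structure volume, which
  is why it is complemented by a surface metric.
* **MDA** (mean distance to agreement): the symmetrized mean surface
  distance in mm.  The surface of a mask is the set of centers of
  foreground voxels with at least one background 6-neighbor (voxels on
  the array edge count their out-of-bounds side as background).  The
  directed distance d(A→B) is the mean over A's surface points of the
  Euclidean distance — anisotropic spacing respected — to the nearest
  surface point of B, and MDA = (d(A→B) + d(B→A)) / 2.

Distances are computed with a spacing-aware exact Euclidean distance
transform evaluated at the other mask's boundary voxels, which equals the
brute-force nearest-neighbor computation over the two boundary point sets.

An empty mask is treated as a data defect: ``dice(empty, empty)`` raises
rather than returning 1, and MDA requires both masks nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_model import MaskVolume

__all__ = [
    "SimilarityResult",
    "boundary_mask",
    "boundary_points",
    "dice",
    "mean_distance_to_agreement",
    "similarity",
]


@dataclass(frozen=True)
class SimilarityResult:
    dsc: float
    mda_mm: float
    volume_a_voxels: int
    volume_b_voxels: int


def _check_compatible(a: MaskVolume, b: MaskVolume) -> None:
    if not a.same_grid(b):
        raise ValueError(
            f"masks live on incompatible grids: {a.grid} vs {b.grid}"
        )


def boundary_mask(mask: MaskVolume) -> np.ndarray:
    """Boolean array marking foreground voxels with a background 6-neighbor."""
    occ = mask.occupancy
    # pad with background so array-edge voxels count their outside as background
    padded = np.pad(occ, 1, mode="constant", constant_values=False)
    interior = np.ones_like(occ, dtype=bool)
    for axis in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    return occ & ~interior


def boundary_points(mask: MaskVolume) -> np.ndarray:
    """Surface voxel centers in mm, shape (n, 3), order (z, y, x)."""
    if mask.is_empty:
        raise ValueError("cannot extract the boundary of an empty mask")
    idx = np.argwhere(boundary_mask(mask))
    spacing = np.asarray(mask.grid.spacing_mm)
    origin = np.asarray(mask.grid.origin_mm)
    return origin + idx * spacing


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|)."""
    _check_compatible(a, b)
    na, nb = a.volume_voxels, b.volume_voxels
    if na == 0 and nb == 0:
        raise ValueError("dice undefined for two empty masks")
    inter = int(np.count_nonzero(a.occupancy & b.occupancy))
    return 2.0 * inter / (na + nb)


def _directed_mean_surface_distance(
    src_boundary: np.ndarray, dst_boundary: np.ndarray, spacing: tuple[float, ...]
) -> float:
    """Mean distance from src boundary voxels to the nearest dst boundary
    voxel, via an exact EDT of the dst boundary set."""
    dt = ndimage.distance_transform_edt(~dst_boundary, sampling=spacing)
    return float(dt[src_boundary].mean())


def mean_distance_to_agreement(a: MaskVolume, b: MaskVolume) -> float:
    """Symmetrized mean surface distance in mm.

    Equal-weight average of the two directed mean boundary distances, not
    weighted by boundary point counts, so the metric is symmetric by
    construction.
    """
    _check_compatible(a, b)
    if a.is_empty or b.is_empty:
        raise ValueError("MDA requires both masks nonempty")
    ba = boundary_mask(a)
    bb = boundary_mask(b)
    spacing = a.grid.spacing_mm
    d_ab = _directed_mean_surface_distance(ba, bb, spacing)
    d_ba = _directed_mean_surface_distance(bb, ba, spacing)
    return 0.5 * (d_ab + d_ba)


def similarity(a: MaskVolume, b: MaskVolume) -> SimilarityResult:
    """DSC and MDA for one mask pair."""
    return SimilarityResult(
        dsc=dice(a, b),
        mda_mm=mean_distance_to_agreement(a, b),
        volume_a_voxels=a.volume_voxels,
        volume_b_voxels=b.volume_voxels,
    )
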