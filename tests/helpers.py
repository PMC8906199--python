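"""Shared test utilities: mask factories and independent brute-force
oracles (deliberately naive implementations, kept separate from the
library code paths they are used to check)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from contourval.io_model import (
    ContourRecord,
    MaskVolume,
    StudyDesign,
    StudyManifest,
    VoxelGrid,
)


def make_mask(occ, spacing=(1.0, 1.0, 1.0)) -> MaskVolume:
    occ = np.asarray(occ)
    return MaskVolume(VoxelGrid(occ.shape, spacing), occ.astype(bool))


def random_blob(seed, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0),
                fill=0.3) -> MaskVolume:
    """Connected-ish random mask from thresholded smoothed noise."""
    rng = np.random.default_rng(seed)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)
    occ = noise > np.quantile(noise, 1 - fill)
    if not occ.any():
        occ[tuple(s // 2 for s in shape)] = True
    return make_mask(occ, spacing)


def sphere_mask(shape, spacing, center_vox, radius_mm) -> MaskVolume:
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                        indexing="ij")
    center_mm = [c * sp for c, sp in zip(center_vox, spacing)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    return make_mask(d2 <= radius_mm ** 2, spacing)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def boundary_scan(mask: MaskVolume) -> np.ndarray:
    """Naive per-voxel 6-neighborhood boundary scan (oracle)."""
    occ = mask.occupancy
    out = np.zeros_like(occ)
    nz, ny, nx = occ.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not occ[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                        out[z, y, x] = True
                        break
                    if not occ[zz, yy, xx]:
                        out[z, y, x] = True
                        break
    return out


def mda_all_pairs(a: MaskVolume, b: MaskVolume) -> float:
    """O(n*m) nearest-neighbor mean surface distance (oracle)."""
    spacing = np.asarray(a.grid.spacing_mm)
    pa = np.argwhere(boundary_scan(a)) * spacing
    pb = np.argwhere(boundary_scan(b)) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def brute_force_em(D, gamma, init_p, init_q, n_iter, clamp=1e-6):
    """Scalar-loop EM with the same updates and initialization as the
    library (oracle).  Returns per-iteration posterior maps and the final
    (p, q)."""
    J, N = D.shape
    p = [float(v) for v in init_p]
    q = [float(v) for v in init_q]
    w_trace = []
    for _ in range(n_iter):
        W = []
        for i in range(N):
            a = gamma
            b = 1.0 - gamma
            for j in range(J):
                if D[j, i]:
                    a *= p[j]
                    b *= 1.0 - q[j]
                else:
                    a *= 1.0 - p[j]
                    b *= q[j]
            W.append(a / (a + b))
        w_trace.append(np.array(W))
        sw = sum(W)
        s1mw = sum(1.0 - w for w in W)
        p = [min(max(sum(W[i] * D[j, i] for i in range(N)) / sw, clamp),
                 1 - clamp) for j in range(J)]
        q = [min(max(sum((1 - W[i]) * (1 - D[j, i]) for i in range(N)) / s1mw,
                     clamp), 1 - clamp) for j in range(J)]
    return w_trace, p, q


# ---------------------------------------------------------------------------
# Manifest builders
# ---------------------------------------------------------------------------

def manifest_with_masks(design: StudyDesign, mask_for_cell,
                        time_for_cell=lambda *cell: 1.0) -> StudyManifest:
    """Complete in-memory manifest; ``mask_for_cell(sub, rat, st, me, se)``
    supplies each mask."""
    records = []
    masks = {}
    for cell in design.cells():
        sub, rat, st, me, se = cell
        records.append(ContourRecord(sub, rat, st, me, se, "",
                                     float(time_for_cell(*cell))))
        masks[cell] = mask_for_cell(*cell)
    return StudyManifest(design=design, records=tuple(records), masks=masks)


def manifest_with_times(design: StudyDesign, time_for_cell) -> StudyManifest:
    """Complete manifest with times only (masks never accessed)."""
    records = [
        ContourRecord(*cell, "", float(time_for_cell(*cell)))
        for cell in design.cells()
    ]
    return StudyManifest(design=design, records=tuple(records), masks=None)
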