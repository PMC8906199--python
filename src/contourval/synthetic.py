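"""Synthetic multi-observer contour studies.

Real validation studies of auto-contouring compare manual (M) and
atlas-assisted (AM) delineations by several observers over repeated
sessions; the underlying planning CTs are rarely shareable.  This module
generates complete stand-in studies with the statistical structure those
analyses assume:

* **ground truth organs** — per-subject smooth blobs: the zero sublevel
  set of a signed ellipsoid level function plus a spatially correlated
  random deformation field, on an anisotropic CT-like grid;
* **rater masks** under two observer models:

  - ``flip``: every true-foreground voxel is kept with probability
    ``p_j`` and every true-background voxel stays background with
    probability ``q_j``, i.i.d. across voxels.  This is exactly the
    generative model STAPLE assumes, so STAPLE parameter recovery can be
    tested end to end.
  - ``boundary``: the rater's contour is a level-set shift of the ground
    truth, ``{x : signed_distance(x) < bias_mm + ε(x)}`` with a per-rater
    systematic bias and a correlated Gaussian noise field ε of pointwise
    sd ``σ`` — observer disagreement concentrated at ambiguous
    boundaries, which is how real contour variability behaves.  AM
    contours use a smaller σ than M contours (editing a proposed contour
    perturbs it less than drawing from scratch).

* **contouring times** — lognormal per timing ROI for M; AM editing times
  are an independent lognormal draw scaled by a multiplier < 1;
* **blind-review decisions** — per (rater, subject, ROI) one paired
  (AM, M) accept/reject draw from an explicit four-cell joint
  distribution.

Every quantity is deterministic given the master seed and the cell
identity: per-cell substreams are derived by hashing the identity tokens
together with the master seed, so regenerating one cell never shifts any
other cell's realization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

from .bias import DecisionRecord, write_decisions_csv
from .io_model import (
    FEMORAL_HEAD_STRUCTURES,
    MERGED_FEMORAL_ROI,
    ContourRecord,
    MaskVolume,
    StudyDesign,
    StudyManifest,
    VoxelGrid,
    write_manifest_csv,
    write_mask,
)

__all__ = [
    "OrganParams",
    "FlipParams",
    "BoundaryParams",
    "TimingParams",
    "DecisionParams",
    "SimulationConfig",
    "generate_ground_truth",
    "perturb_flip",
    "perturb_boundary",
    "simulate_times",
    "simulate_decisions",
    "simulate_study",
    "signed_distance_mm",
    "default_grid",
]

# CT-like geometry: 512-matrix / 600 mm FOV gives 1.17 mm in-plane pixels
# and 3 mm slices; cropped to a 96 x 96 in-plane / 64-slice block so that a
# full 600-mask study stays desk-scale.  Array order is (z, y, x).
DEFAULT_SHAPE = (64, 96, 96)
DEFAULT_SPACING = (3.0, 1.17, 1.17)


def default_grid() -> VoxelGrid:
    return VoxelGrid(shape=DEFAULT_SHAPE, spacing_mm=DEFAULT_SPACING)


@dataclass(frozen=True)
class OrganParams:
    """Ellipsoid center/radii in mm (z, y, x order) plus the amplitude and
    correlation length of the per-subject boundary deformation field."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    deform_amplitude_mm: float = 3.0
    deform_corr_mm: float = 15.0


def _default_organs() -> dict[str, OrganParams]:
    # laid out inside the default 192 x 112 x 112 mm grid with >= 5 mm
    # clearance; rough pelvis-scale proportions (bladder and PLN large,
    # rectum elongated cranio-caudally, femoral heads near-spherical)
    return {
        "bladder": OrganParams((96, 52, 56), (24, 28, 28)),
        "rectum": OrganParams((88, 78, 56), (42, 12, 12)),
        "PLN": OrganParams((108, 50, 56), (38, 26, 26), deform_amplitude_mm=4.0),
        "femoral_head_L": OrganParams((90, 60, 27), (17, 17, 17),
                                      deform_amplitude_mm=1.5),
        "femoral_head_R": OrganParams((90, 60, 85), (17, 17, 17),
                                      deform_amplitude_mm=1.5),
    }


@dataclass(frozen=True)
class FlipParams:
    """Per-rater (sensitivity, specificity) for the i.i.d. flip model; AM
    error rates are the M rates scaled toward perfect by ``am_error_scale``:
    ``1 - (1 - rate) * am_error_scale``."""

    p: tuple[float, ...] = (0.95, 0.93, 0.90, 0.88, 0.85)
    q: tuple[float, ...] = (0.99, 0.99, 0.99, 0.99, 0.99)
    am_error_scale: float = 0.5


@dataclass(frozen=True)
class BoundaryParams:
    """Per-rater systematic boundary bias (mm, retained across that rater's
    sessions) and the noise-field magnitude for each method."""

    bias_mm: tuple[float, ...] = (-1.5, -0.75, 0.0, 0.75, 1.5)
    sigma_m_mm: float = 2.5
    sigma_am_mm: float = 1.25
    corr_mm: float = 20.0


@dataclass(frozen=True)
class TimingParams:
    """Lognormal manual-contouring time per timing ROI and the AM editing
    multiplier.  The default ROI means (min) sit in the range reported for
    pelvis structures: rectum ~4, bladder ~4.2, nodes ~19, femoral heads
    ~8.7; sigma 0.3 gives realistic right-skewed spread."""

    mu_log: Mapping[str, float] = field(default_factory=lambda: {
        "bladder": float(np.log(4.2) - 0.045),
        "rectum": float(np.log(4.0) - 0.045),
        "PLN": float(np.log(18.7) - 0.045),
        MERGED_FEMORAL_ROI: float(np.log(8.7) - 0.045),
    })
    sigma_log: float = 0.3
    am_multiplier: float = 0.55

    def __post_init__(self) -> None:
        if not (0.0 < self.am_multiplier <= 1.0):
            raise ValueError("am_multiplier must be in (0, 1]")


@dataclass(frozen=True)
class DecisionParams:
    """Joint probabilities of the paired (AM decision, M decision) cells,
    order (nn, ny, yn, yy); must sum to 1.  Defaults reproduce the regime
    of a mostly-accepted contour set with mild discordance favoring AM."""

    joint: tuple[float, float, float, float] = (3 / 96, 4 / 96, 8 / 96, 81 / 96)
    n_bias_raters: int = 4

    def __post_init__(self) -> None:
        if abs(sum(self.joint) - 1.0) > 1e-12:
            raise ValueError(f"decision joint probabilities must sum to 1, "
                             f"got sum {sum(self.joint)}")
        if any(p < 0 for p in self.joint):
            raise ValueError("decision probabilities must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    design: StudyDesign = field(default_factory=StudyDesign.default)
    grid: VoxelGrid = field(default_factory=default_grid)
    organ_params: Mapping[str, OrganParams] = field(default_factory=_default_organs)
    rater_model: str = "boundary"
    flip_params: FlipParams = field(default_factory=FlipParams)
    boundary_params: BoundaryParams = field(default_factory=BoundaryParams)
    timing_params: TimingParams = field(default_factory=TimingParams)
    decision_params: DecisionParams = field(default_factory=DecisionParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rater_model not in ("flip", "boundary"):
            raise ValueError("rater_model must be 'flip' or 'boundary'")
        for s in self.design.structures:
            if s not in self.organ_params:
                raise ValueError(f"no organ parameters for structure {s!r}")


# ---------------------------------------------------------------------------
# Seeding: stable per-cell substreams
# ---------------------------------------------------------------------------

def _substream(master_seed: int, *identity) -> np.random.Generator:
    """Independent generator for one simulation cell: the identity tokens
    are CRC-hashed so regenerating one cell never shifts another."""
    keys = [zlib.crc32(str(tok).encode("utf-8")) for tok in identity]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % (2**31), *keys]))


# ---------------------------------------------------------------------------
# Random fields and ground truth
# ---------------------------------------------------------------------------

def _gaussian_field(shape: tuple[int, ...], spacing: tuple[float, ...],
                    corr_mm: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random field with pointwise sd ``sd``: white noise
    smoothed by a Gaussian kernel of the given correlation length, then
    rescaled to the target pointwise standard deviation."""
    white = rng.standard_normal(shape)
    if corr_mm <= 0:
        return white * sd
    sigmas = [corr_mm / sp for sp in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigmas, mode="reflect")
    scale = smooth.std()
    if scale == 0:
        return np.zeros(shape)
    return smooth * (sd / scale)


def _coords_mm(grid: VoxelGrid) -> list[np.ndarray]:
    return [
        grid.origin_mm[ax] + np.arange(grid.shape[ax]) * grid.spacing_mm[ax]
        for ax in range(3)
    ]


def generate_ground_truth(config: SimulationConfig, structure: str,
                          subject_seed: int) -> MaskVolume:
    """Per-subject organ: zero sublevel set of a signed ellipsoid level
    function plus a correlated deformation field.

    The level function is scaled to approximate mm near the surface, so
    the deformation amplitude is interpretable as a boundary displacement
    in mm; amplitude 0 yields the exact voxelized ellipsoid.
    """
    params = config.organ_params[structure]
    grid = config.grid
    center = np.asarray(params.center_mm)
    radii = np.asarray(params.radii_mm)
    for ax in range(3):
        extent = grid.shape[ax] * grid.spacing_mm[ax]
        if center[ax] - radii[ax] < 5.0 or center[ax] + radii[ax] > extent - 5.0:
            raise ValueError(
                f"organ {structure!r} does not fit inside the grid with "
                f">= 5 mm clearance on axis {ax}"
            )
    zs, ys, xs = _coords_mm(grid)
    rho = np.sqrt(
        ((zs[:, None, None] - center[0]) / radii[0]) ** 2
        + ((ys[None, :, None] - center[1]) / radii[1]) ** 2
        + ((xs[None, None, :] - center[2]) / radii[2]) ** 2
    )
    # (rho - 1) * mean radius ~ signed boundary offset in mm
    level = (rho - 1.0) * float(radii.mean())
    if params.deform_amplitude_mm > 0:
        rng = _substream(config.seed, "gt", structure, subject_seed)
        level = level + _gaussian_field(grid.shape, grid.spacing_mm,
                                        params.deform_corr_mm,
                                        params.deform_amplitude_mm, rng)
    mask = MaskVolume(grid=grid, occupancy=level < 0)
    if mask.is_empty:
        raise ValueError(f"degenerate ground truth for {structure!r}: empty mask")
    return mask


# ---------------------------------------------------------------------------
# Observer models
# ---------------------------------------------------------------------------

def perturb_flip(gt: MaskVolume, p: float, q: float,
                 seed: int | np.random.Generator) -> MaskVolume:
    """I.i.d. label noise: foreground kept w.p. ``p``, background kept
    w.p. ``q`` — the exact generative counterpart of the STAPLE model."""
    if not (0.0 < p <= 1.0 and 0.0 < q <= 1.0):
        raise ValueError(f"p and q must be in (0, 1], got p={p}, q={q}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(gt.grid.shape)
    occ = np.where(gt.occupancy, u < p, u >= q)
    return MaskVolume(grid=gt.grid, occupancy=occ)


def signed_distance_mm(mask: MaskVolume) -> np.ndarray:
    """Signed Euclidean distance to the mask surface in mm: negative
    inside the foreground, positive outside."""
    occ = mask.occupancy
    spacing = mask.grid.spacing_mm
    d_out = ndimage.distance_transform_edt(~occ, sampling=spacing)
    d_in = ndimage.distance_transform_edt(occ, sampling=spacing)
    return d_out - d_in


def perturb_boundary(gt: MaskVolume, bias_mm: float, sigma_mm: float,
                     corr_mm: float, seed: int | np.random.Generator,
                     _sdist: np.ndarray | None = None) -> MaskVolume:
    """Level-set observer model: ``{x : signed_distance(x) < bias + ε(x)}``
    with ε a correlated zero-mean field of pointwise sd ``sigma_mm``.

    ``bias = sigma = 0`` reproduces the input exactly; a pure positive
    bias is a uniform outward shift (dilation).  ``_sdist`` lets callers
    reuse a precomputed signed-distance map of ``gt``.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be nonnegative")
    sd = signed_distance_mm(gt) if _sdist is None else _sdist
    if sigma_mm == 0:
        return MaskVolume(grid=gt.grid, occupancy=sd < bias_mm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # the perturbation only matters near the surface: evaluate the noise
    # field on a band around the ground-truth bounding box
    reach_mm = abs(bias_mm) + 5.0 * sigma_mm
    band = _band_box(gt, reach_mm + corr_mm)
    eps = _gaussian_field(tuple(s.stop - s.start for s in band),
                          gt.grid.spacing_mm, corr_mm, sigma_mm, rng)
    occ = sd < bias_mm
    occ[band] = sd[band] < bias_mm + eps
    return MaskVolume(grid=gt.grid, occupancy=occ)


def _band_box(mask: MaskVolume, margin_mm: float) -> tuple[slice, slice, slice]:
    occ = mask.occupancy
    slices = []
    for axis in range(3):
        proj = occ.any(axis=tuple(ax for ax in range(3) if ax != axis))
        nz = np.nonzero(proj)[0]
        pad = int(np.ceil(margin_mm / mask.grid.spacing_mm[axis])) + 1
        lo = max(int(nz[0]) - pad, 0)
        hi = min(int(nz[-1]) + pad, mask.grid.shape[axis] - 1)
        slices.append(slice(lo, hi + 1))
    return tuple(slices)


# ---------------------------------------------------------------------------
# Times and decisions
# ---------------------------------------------------------------------------

def simulate_times(config: SimulationConfig, seed: int | None = None
                   ) -> dict[tuple[str, str, str, str, int], float]:
    """Times in minutes keyed by (subject, rater, timing ROI, method,
    session).  Manual times are lognormal per ROI; AM editing times are an
    independent lognormal draw scaled by the AM multiplier."""
    master = config.seed if seed is None else seed
    tp = config.timing_params
    design = config.design
    times: dict[tuple[str, str, str, str, int], float] = {}
    for sub in design.subjects:
        for rat in design.raters:
            for roi in design.timing_rois:
                mu = tp.mu_log[roi]
                for se in design.sessions:
                    for me in design.methods:
                        rng = _substream(master, "time", sub, rat, roi, me, se)
                        t = float(np.exp(rng.normal(mu, tp.sigma_log)))
                        if me == "AM":
                            t *= tp.am_multiplier
                        times[(sub, rat, roi, me, se)] = t
    return times


def simulate_decisions(config: SimulationConfig, seed: int | None = None
                       ) -> list[DecisionRecord]:
    """Paired blind-review decisions: for each (bias rater, subject, ROI)
    one draw of the (AM, M) decision pair from the four-cell joint."""
    master = config.seed if seed is None else seed
    dp = config.decision_params
    design = config.design
    raters = design.raters[: dp.n_bias_raters]
    cells = ["nn", "ny", "yn", "yy"]
    probs = np.asarray(dp.joint, dtype=float)
    records: list[DecisionRecord] = []
    for rat in raters:
        for sub in design.subjects:
            for roi in design.timing_rois:
                rng = _substream(master, "decision", rat, sub, roi)
                cell = cells[int(rng.choice(4, p=probs))]
                am_dec = "NO" if cell[0] == "n" else "YES"
                m_dec = "NO" if cell[1] == "n" else "YES"
                records.append(DecisionRecord(rat, sub, roi, "AM", am_dec))
                records.append(DecisionRecord(rat, sub, roi, "M", m_dec))
    return records


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

def _rater_mask(config: SimulationConfig, gt: MaskVolume, sdist: np.ndarray | None,
                structure: str, subject: str, rater_idx: int, rater: str,
                method: str, session: int) -> MaskVolume:
    rng = _substream(config.seed, "mask", subject, rater, structure, method, session)
    if config.rater_model == "flip":
        fp = config.flip_params
        p = fp.p[rater_idx % len(fp.p)]
        q = fp.q[rater_idx % len(fp.q)]
        if method == "AM":
            p = 1.0 - (1.0 - p) * fp.am_error_scale
            q = 1.0 - (1.0 - q) * fp.am_error_scale
        return perturb_flip(gt, p, q, rng)
    bp = config.boundary_params
    bias = bp.bias_mm[rater_idx % len(bp.bias_mm)]
    sigma = bp.sigma_m_mm if method == "M" else bp.sigma_am_mm
    return perturb_boundary(gt, bias, sigma, bp.corr_mm, rng, _sdist=sdist)


def simulate_study(config: SimulationConfig, out_dir: str | Path | None = None
                   ) -> StudyManifest:
    """Generate a complete study: all masks, times and decisions.

    With ``out_dir`` set, masks are written as NIfTI, plus ``manifest.csv``
    and ``decisions.csv``; the returned manifest also carries the masks
    in memory so analyses can run without re-reading files.  Session-to-
    session intra-observer variation is a fresh noise realization with
    the rater's systematic bias retained.
    """
    design = config.design
    times = simulate_times(config)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        (out_path / "masks").mkdir(parents=True, exist_ok=True)

    masks: dict[tuple, MaskVolume] = {}
    records: list[ContourRecord] = []
    for sub_idx, sub in enumerate(design.subjects):
        for structure in design.structures:
            gt = generate_ground_truth(config, structure, sub_idx)
            sdist = (signed_distance_mm(gt)
                     if config.rater_model == "boundary" else None)
            for rat_idx, rat in enumerate(design.raters):
                for me in design.methods:
                    for se in design.sessions:
                        mask = _rater_mask(config, gt, sdist, structure, sub,
                                           rat_idx, rat, me, se)
                        key = (sub, rat, structure, me, se)
                        masks[key] = mask
                        roi = design.timing_roi_of(structure)
                        t_roi = times[(sub, rat, roi, me, se)]
                        # each femoral head carries half the merged-ROI time
                        # so the per-ROI sum identity holds exactly
                        t = t_roi / 2 if structure in FEMORAL_HEAD_STRUCTURES else t_roi
                        mask_path = ""
                        if out_path is not None:
                            fname = f"{sub}_{rat}_{structure}_{me}{se}.nii.gz"
                            mask_path = str(out_path / "masks" / fname)
                            write_mask(mask, mask_path)
                        records.append(ContourRecord(sub, rat, structure, me,
                                                     se, mask_path, t))

    manifest = StudyManifest(design=design, records=tuple(records), masks=masks)
    if out_path is not None:
        write_manifest_csv(records, out_path / "manifest.csv")
        write_decisions_csv(simulate_decisions(config), out_path / "decisions.csv")
    return manifest
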