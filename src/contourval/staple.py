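"""Binary STAPLE label fusion (Simultaneous Truth and Performance Level
Estimation).

Given masks of the same structure drawn by several raters, STAPLE treats
the unknown true segmentation ``T`` as a latent per-voxel binary variable
and each rater ``j`` as a noisy channel with sensitivity ``p_j``
(probability of marking a true-foreground voxel foreground) and
specificity ``q_j`` (probability of leaving a true-background voxel
background), independently per voxel.  Expectation-maximization
alternates:

* E-step: posterior foreground probability of each voxel,
  ``W_i = a_i / (a_i + b_i)`` with
  ``a_i = γ · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij}`` and
  ``b_i = (1−γ) · Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}``,
  where ``D_ij`` is rater j's label at voxel i and ``γ`` the foreground
  prior;
* M-step: ``p_j = Σ_i W_i D_ij / Σ_i W_i`` and
  ``q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)``.

Choices fixed here (all surfaced in :class:`StapleConfig`): initial
``p = q = 0.99``; ``γ`` defaults to the mean foreground fraction of the
rater masks within the crop region and is held fixed across iterations;
convergence when the relative change of ``Σ_i W_i`` drops below ``tol``;
consensus by thresholding ``W`` at 0.5 with ties included as foreground.
Computation is restricted to a bounding box around the union of the rater
masks plus a margin (default 10 mm) — without the crop, the vast empty
background dominates ``γ`` and the specificity estimates.  Per-rater
probability products are accumulated in log space and performance
parameters are clamped to ``[1e-6, 1 − 1e-6]`` each M-step to avoid
degenerate absorbing states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_model import MaskVolume

__all__ = [
    "RaterPerformance",
    "StapleConfig",
    "StapleResult",
    "crop_region",
    "staple",
    "build_reference",
]

_CLAMP = 1e-6


@dataclass(frozen=True)
class RaterPerformance:
    """Estimated sensitivity p and specificity q of one rater."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0 and 0.0 < self.q <= 1.0):
            raise ValueError(f"sensitivity/specificity must be in (0, 1], got {self}")


@dataclass(frozen=True)
class StapleConfig:
    init_p: float = 0.99
    init_q: float = 0.99
    prior_gamma: float | str = "auto"
    max_iter: int = 100
    tol: float = 1e-6
    threshold: float = 0.5
    crop_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if isinstance(self.prior_gamma, str):
            if self.prior_gamma != "auto":
                raise ValueError("prior_gamma must be a real in (0,1) or 'auto'")
        elif not (0.0 < self.prior_gamma < 1.0):
            raise ValueError(f"prior_gamma must be in (0, 1), got {self.prior_gamma}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")
        if self.crop_margin_mm < 0:
            raise ValueError("crop_margin_mm must be nonnegative")


@dataclass
class StapleResult:
    probability: np.ndarray            # W over the crop region, shape = crop box
    crop: tuple[slice, slice, slice]   # crop box in full-grid voxel indices
    consensus: MaskVolume              # thresholded consensus on the full grid
    performances: dict[str, RaterPerformance] = field(default_factory=dict)
    iterations: int = 0
    converged: bool = False
    loglik_trace: tuple[float, ...] = ()
    gamma: float = 0.5


def crop_region(masks: list[MaskVolume], margin_mm: float) -> tuple[slice, slice, slice]:
    """Bounding box of the union of foregrounds, dilated by
    ``ceil(margin_mm / spacing)`` voxels per axis and clipped to the grid."""
    if not masks:
        raise ValueError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.is_compatible(grid):
            raise ValueError("masks live on incompatible grids")
    union = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        union |= m.occupancy
    if not union.any():
        raise ValueError("all masks are empty; no crop region exists")
    slices = []
    for axis in range(3):
        proj = union.any(axis=tuple(ax for ax in range(3) if ax != axis))
        nz = np.nonzero(proj)[0]
        pad = math.ceil(margin_mm / grid.spacing_mm[axis])
        lo = max(int(nz[0]) - pad, 0)
        hi = min(int(nz[-1]) + pad, grid.shape[axis] - 1)
        slices.append(slice(lo, hi + 1))
    return tuple(slices)


def _em(D: np.ndarray, gamma: float, init_p: np.ndarray, init_q: np.ndarray,
        max_iter: int, tol: float, w_trace: list | None = None
        ) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool, list[float]]:
    """Core EM on a (raters, voxels) binary matrix.  Returns (W, p, q,
    iterations, converged, loglik trace).  If ``w_trace`` is a list, the
    posterior map of every E-step is appended to it (diagnostics only)."""
    Df = D.astype(np.float64)
    p = init_p.astype(np.float64).copy()
    q = init_q.astype(np.float64).copy()
    log_gamma = math.log(gamma)
    log_1m_gamma = math.log1p(-gamma)
    prev_sum_w = None
    trace: list[float] = []
    W = np.full(D.shape[1], gamma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step, log space: a_i ~ prior x sensitivity terms, b_i ~ specificity
        log_a = log_gamma + Df.T @ np.log(p) + (1.0 - Df.T) @ np.log1p(-p)
        log_b = log_1m_gamma + Df.T @ np.log1p(-q) + (1.0 - Df.T) @ np.log(q)
        m = np.maximum(log_a, log_b)
        log_norm = m + np.log(np.exp(log_a - m) + np.exp(log_b - m))
        W = np.exp(log_a - log_norm)
        if w_trace is not None:
            w_trace.append(W.copy())
        trace.append(float(log_norm.sum()))
        sum_w = float(W.sum())
        if prev_sum_w is not None:
            denom = max(abs(prev_sum_w), np.finfo(float).tiny)
            if abs(sum_w - prev_sum_w) / denom < tol:
                converged = True
                break
        prev_sum_w = sum_w
        # M-step with clamping away from {0, 1}
        sw = W.sum()
        s1mw = (1.0 - W).sum()
        p = np.clip((Df @ W) / max(sw, np.finfo(float).tiny), _CLAMP, 1.0 - _CLAMP)
        q = np.clip(((1.0 - Df) @ (1.0 - W)) / max(s1mw, np.finfo(float).tiny),
                    _CLAMP, 1.0 - _CLAMP)
    return W, p, q, it, converged, trace


def staple(masks: list[MaskVolume], config: StapleConfig = StapleConfig(),
           rater_ids: list[str] | None = None) -> StapleResult:
    """Run binary STAPLE EM over >= 2 rater masks on compatible grids."""
    if len(masks) < 2:
        raise ValueError(f"STAPLE needs at least 2 raters, got {len(masks)}")
    grid = masks[0].grid
    for m in masks[1:]:
        if not m.grid.is_compatible(grid):
            raise ValueError("rater masks live on incompatible grids")
    if rater_ids is None:
        rater_ids = [f"rater{j}" for j in range(len(masks))]
    if len(rater_ids) != len(masks):
        raise ValueError("rater_ids length must match masks")

    crop = crop_region(masks, config.crop_margin_mm)
    D = np.stack([m.occupancy[crop].reshape(-1) for m in masks]).astype(np.uint8)

    if config.prior_gamma == "auto":
        gamma = float(D.mean())
    else:
        gamma = float(config.prior_gamma)
    gamma = min(max(gamma, _CLAMP), 1.0 - _CLAMP)

    init_p = np.full(len(masks), config.init_p)
    init_q = np.full(len(masks), config.init_q)
    W, p, q, iterations, converged, trace = _em(
        D, gamma, init_p, init_q, config.max_iter, config.tol
    )
    if not np.isfinite(W).all():
        raise FloatingPointError("STAPLE produced non-finite posterior weights")

    crop_shape = tuple(s.stop - s.start for s in crop)
    prob = W.reshape(crop_shape)
    consensus_arr = np.zeros(grid.shape, dtype=bool)
    consensus_arr[crop] = prob >= config.threshold  # ties count as foreground
    return StapleResult(
        probability=prob,
        crop=crop,
        consensus=MaskVolume(grid=grid, occupancy=consensus_arr),
        performances={
            rid: RaterPerformance(p=float(pj), q=float(qj))
            for rid, pj, qj in zip(rater_ids, p, q)
        },
        iterations=iterations,
        converged=converged,
        loglik_trace=tuple(trace),
        gamma=gamma,
    )


def build_reference(masks_by_rater: dict[str, MaskVolume],
                    config: StapleConfig = StapleConfig()) -> MaskVolume:
    """Fuse one structure's rater masks into the shared reference contour.

    Deterministic given inputs and config; invariant to rater ordering.
    Raters are processed in sorted-id order to make that explicit.
    """
    rater_ids = sorted(masks_by_rater)
    result = staple([masks_by_rater[r] for r in rater_ids], config,
                    rater_ids=rater_ids)
    return result.consensus
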