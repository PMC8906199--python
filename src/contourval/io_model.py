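"""Core data model, NIfTI mask I/O, and study-manifest handling.

A contour-validation study is a full cross-product design: every
(subject, rater, structure, method, session) cell holds exactly one binary
structure mask plus a recorded contouring/editing time.  Methods are
``M`` (manual delineation from scratch) and ``AM`` (automatic contour,
manually edited); sessions 1 and 2 are repeated delineations by the same
observer.  Masks live on per-subject voxel grids with anisotropic spacing
in mm; masks that are compared to each other must share a grid — they are
never resampled.

Conventions used throughout the package:

* array index order is ``(slice, row, col)`` = ``(z, y, x)``; the spacing
  tuple uses the same order;
* voxel indices are 0-based; the physical coordinate of voxel ``v`` is
  ``origin + v * spacing`` (voxel-center convention);
* a stored voxel is foreground iff its value is ``> 0``, so the
  ``{0, 1}`` and ``{0, 255}`` label dialects load identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "MaskVolume",
    "ContourRecord",
    "StudyDesign",
    "StudyManifest",
    "ManifestError",
    "read_mask",
    "write_mask",
    "load_manifest",
    "write_manifest_csv",
    "DEFAULT_STRUCTURES",
    "DEFAULT_TIMING_ROIS",
    "FEMORAL_HEAD_STRUCTURES",
    "MERGED_FEMORAL_ROI",
]

SPACING_ATOL_MM = 1e-6

DEFAULT_STRUCTURES = ("bladder", "rectum", "PLN", "femoral_head_L", "femoral_head_R")
FEMORAL_HEAD_STRUCTURES = ("femoral_head_L", "femoral_head_R")
MERGED_FEMORAL_ROI = "femoral_heads"
DEFAULT_TIMING_ROIS = ("bladder", "rectum", "PLN", MERGED_FEMORAL_ROI)

METHODS = ("M", "AM")
SESSIONS = (1, 2)


class ManifestError(ValueError):
    """Raised when a manifest violates the cross-product study design."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice: shape (z, y, x), spacing and origin in mm."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        origin = tuple(float(s) for s in self.origin_mm)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be 3-vectors")
        if any(s < 1 for s in shape):
            raise ValueError(f"all grid extents must be >= 1, got {shape}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"all voxel spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    def is_compatible(self, other: "VoxelGrid") -> bool:
        """Same shape and spacing equal within 1e-6 mm (origin is irrelevant
        for mask comparison on a shared planning CT)."""
        return self.shape == other.shape and all(
            abs(a - b) <= SPACING_ATOL_MM
            for a, b in zip(self.spacing_mm, other.spacing_mm)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class MaskVolume:
    """Binary occupancy on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.shape:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid {self.grid.shape}"
            )
        if occ.dtype != bool:
            if not np.isfinite(occ).all():
                raise ValueError("mask contains non-finite voxel values")
            occ = occ > 0
        self.occupancy = occ

    @property
    def volume_voxels(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_mm3(self) -> float:
        return self.volume_voxels * self.grid.voxel_volume_mm3

    @property
    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def same_grid(self, other: "MaskVolume") -> bool:
        return self.grid.is_compatible(other.grid)


@dataclass(frozen=True)
class ContourRecord:
    """One cell of the study design: a mask reference plus its recorded time.

    ``time_min`` is the contouring time for method M and the editing time
    for method AM, in decimal minutes.
    """

    subject_id: str
    rater_id: str
    structure: str
    method: str
    session: int
    mask_path: str
    time_min: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}; expected one of {SESSIONS}")
        if not (self.time_min >= 0):
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        return (self.subject_id, self.rater_id, self.structure, self.method, self.session)


@dataclass(frozen=True)
class StudyDesign:
    """The cross-product skeleton of the study.

    ``timing_rois`` is the structure list with the two femoral heads merged
    into a single ``femoral_heads`` token, since their times are analyzed
    as one region of interest.
    """

    subjects: tuple[str, ...]
    raters: tuple[str, ...]
    structures: tuple[str, ...] = DEFAULT_STRUCTURES
    methods: tuple[str, ...] = METHODS
    sessions: tuple[int, ...] = SESSIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "raters", tuple(self.raters))
        object.__setattr__(self, "structures", tuple(self.structures))
        for name, seq in (("subjects", self.subjects), ("raters", self.raters),
                          ("structures", self.structures)):
            if len(seq) == 0:
                raise ValueError(f"design needs at least one entry in {name}")
            if len(set(seq)) != len(seq):
                raise ValueError(f"duplicate tokens in {name}: {seq}")

    @classmethod
    def default(cls) -> "StudyDesign":
        """6 subjects x 5 raters x 5 structures x 2 methods x 2 sessions."""
        return cls(
            subjects=tuple(f"subj{i:02d}" for i in range(1, 7)),
            raters=tuple(f"RO{i}" for i in range(1, 6)),
        )

    @property
    def timing_rois(self) -> tuple[str, ...]:
        rois: list[str] = []
        for s in self.structures:
            if s in FEMORAL_HEAD_STRUCTURES:
                if MERGED_FEMORAL_ROI not in rois:
                    rois.append(MERGED_FEMORAL_ROI)
            else:
                rois.append(s)
        return tuple(rois)

    def timing_roi_of(self, structure: str) -> str:
        return MERGED_FEMORAL_ROI if structure in FEMORAL_HEAD_STRUCTURES else structure

    def cells(self) -> list[tuple[str, str, str, str, int]]:
        """All (subject, rater, structure, method, session) cells."""
        return [
            (sub, rat, st, me, se)
            for sub in self.subjects
            for rat in self.raters
            for st in self.structures
            for me in self.methods
            for se in self.sessions
        ]

    @property
    def n_records(self) -> int:
        return (len(self.subjects) * len(self.raters) * len(self.structures)
                * len(self.methods) * len(self.sessions))

    @property
    def n_per_set(self) -> int:
        """Records per contour set (one method, one session)."""
        return len(self.subjects) * len(self.raters) * len(self.structures)


@dataclass
class StudyManifest:
    """A validated, complete set of contour records for a design.

    ``masks`` optionally maps record keys to in-memory :class:`MaskVolume`
    objects so that simulated studies can be analyzed without touching disk;
    otherwise masks are loaded from ``mask_path``.
    """

    design: StudyDesign
    records: tuple[ContourRecord, ...]
    masks: Mapping[tuple, MaskVolume] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        validate_records(self.design, self.records)
        self._by_key = {r.key: r for r in self.records}

    def record(self, subject: str, rater: str, structure: str,
               method: str, session: int) -> ContourRecord:
        return self._by_key[(subject, rater, structure, method, session)]

    def get_mask(self, record: ContourRecord) -> MaskVolume:
        if self.masks is not None:
            return self.masks[record.key]
        return read_mask(record.mask_path)

    def set_counts(self) -> dict[tuple[str, int], int]:
        """Record count per (method, session) contour set."""
        counts: dict[tuple[str, int], int] = {}
        for r in self.records:
            counts[(r.method, r.session)] = counts.get((r.method, r.session), 0) + 1
        return counts


def validate_records(design: StudyDesign, records: Sequence[ContourRecord]) -> None:
    """Records must cover the design cross-product exactly once each."""
    expected = set(design.cells())
    seen: set[tuple] = set()
    for r in records:
        if r.subject_id not in design.subjects:
            raise ManifestError(f"unknown subject {r.subject_id!r}")
        if r.rater_id not in design.raters:
            raise ManifestError(f"unknown rater {r.rater_id!r}")
        if r.structure not in design.structures:
            raise ManifestError(f"unknown structure {r.structure!r}")
        if r.key in seen:
            raise ManifestError(f"duplicate record for cell {r.key}")
        if r.key not in expected:
            raise ManifestError(f"record outside design cross-product: {r.key}")
        seen.add(r.key)
    missing = expected - seen
    if missing:
        cell = sorted(missing)[0]
        raise ManifestError(
            f"manifest is missing {len(missing)} cell(s) of the design "
            f"cross-product, e.g. (subject={cell[0]}, rater={cell[1]}, "
            f"structure={cell[2]}, method={cell[3]}, session={cell[4]})"
        )


# ---------------------------------------------------------------------------
# NIfTI mask I/O
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> MaskVolume:
    """Load a 3D NIfTI volume as a binary mask.

    Foreground is any stored value ``> 0``; shape and per-axis spacing come
    from the header.  Orientation information beyond per-axis spacing is
    ignored: masks to be compared must already share a grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file does not exist: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask image, got {data.ndim}D from {path}")
    if not np.isfinite(data).all():
        raise ValueError(f"mask contains non-finite voxel values: {path}")
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape, spacing_mm=tuple(float(z) for z in zooms))
    return MaskVolume(grid=grid, occupancy=data > 0)


def write_mask(mask: MaskVolume, path: str | Path) -> Path:
    """Write a mask as uint8 NIfTI with a diagonal spacing affine.

    Round-trips losslessly through :func:`read_mask` on occupancy, shape
    and spacing (within 1e-6 mm).
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(mask.grid.spacing_mm) + [1.0])
    affine[:3, 3] = mask.grid.origin_mm
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.header.set_zooms(mask.grid.spacing_mm)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Manifest CSV
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "rater_id", "structure", "method",
                    "session", "mask_path", "time_min")


def load_manifest(manifest_csv: str | Path, design: StudyDesign) -> StudyManifest:
    """Load and validate a manifest CSV against a study design.

    The CSV is comma-separated UTF-8 with a required header
    ``subject_id,rater_id,structure,method,session,mask_path,time_min``.
    """
    manifest_csv = Path(manifest_csv)
    records: list[ContourRecord] = []
    with open(manifest_csv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(MANIFEST_COLUMNS):
            raise ManifestError(
                f"manifest header must be exactly {','.join(MANIFEST_COLUMNS)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            try:
                session = int(row["session"])
            except ValueError as exc:
                raise ManifestError(f"non-integer session {row['session']!r}") from exc
            try:
                time_min = float(row["time_min"])
            except ValueError as exc:
                raise ManifestError(f"non-numeric time_min {row['time_min']!r}") from exc
            if time_min < 0:
                raise ManifestError(
                    f"negative time {time_min} for subject={row['subject_id']}"
                )
            records.append(
                ContourRecord(
                    subject_id=row["subject_id"],
                    rater_id=row["rater_id"],
                    structure=row["structure"],
                    method=row["method"],
                    session=session,
                    mask_path=row["mask_path"],
                    time_min=time_min,
                )
            )
    return StudyManifest(design=design, records=tuple(records))


def write_manifest_csv(records: Iterable[ContourRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([r.subject_id, r.rater_id, r.structure, r.method,
                             r.session, r.mask_path, repr(r.time_min)])
    return path
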