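"""Volumetric image / mesh / cohort-manifest I/O and manifest bookkeeping.

All grids follow one declared axis convention:

* axis 0 — patient left--right, index increasing toward the patient's **left**
* axis 1 — anterior--posterior
* axis 2 — inferior--superior (toward the head)

Volumes and masks live on disk as NIfTI-1, meshes as binary STL, and the
cohort manifest as a UTF-8 CSV with columns
``case_id,image,left_mask,right_mask,split``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

#: Grid axis that runs along the patient left-right direction.
AXIS_LR = 0
#: Grid axis that runs anterior-posterior.
AXIS_AP = 1
#: Grid axis that runs inferior-superior (the long axis of the leg).
AXIS_IS = 2

SPLITS = ("train", "val", "test", "unassigned")


class FormatError(ValueError):
    """File exists but is not a readable volume/mesh of the expected kind."""


class ShapeError(ValueError):
    """Grid rank or shape violates a contract."""


class EmptyManifestError(ValueError):
    """A filtering or generation step produced a manifest with no records."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume data must be rank 3, got rank {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Mask(Volume):
    """A binary grid aligned to a parent :class:`Volume`."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class SurfaceMesh:
    """Triangle mesh in physical (mm) coordinates."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of vertex range")
        if len(self.faces):
            f = self.faces
            degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degenerate.any():
                raise ValueError("mesh contains degenerate faces")

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class CaseRecord:
    """One cohort case: image path plus whichever fibula masks exist."""

    case_id: str
    image_path: str
    left_mask_path: Optional[str] = None
    right_mask_path: Optional[str] = None
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.left_mask_path is None and self.right_mask_path is None:
            raise ValueError(f"case {self.case_id}: at least one mask path is required")
        if self.split not in SPLITS:
            raise ValueError(f"unknown split {self.split!r}")

    @property
    def has_both(self) -> bool:
        return self.left_mask_path is not None and self.right_mask_path is not None

    @property
    def available_sides(self) -> list[str]:
        sides = []
        if self.left_mask_path is not None:
            sides.append("left")
        if self.right_mask_path is not None:
            sides.append("right")
        return sides

    def mask_path(self, side: str) -> Optional[str]:
        return self.left_mask_path if side == "left" else self.right_mask_path


@dataclass
class Manifest:
    """Ordered collection of :class:`CaseRecord` with unique case ids."""

    records: list[CaseRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.case_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("case_ids must be unique within a manifest")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.records if r.split == split], self.provenance)


# ---------------------------------------------------------------------------
# volume / mask I/O (NIfTI-1)
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI volume; spacing and origin are taken from the header."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a rank-3 grid, got rank {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume(data=data, spacing=spacing, origin=origin)


def write_mask(mask: Mask, path: str | Path) -> None:
    write_volume(Volume(mask.data.astype(np.uint8), mask.spacing, mask.origin), path)


def read_mask(path: str | Path) -> Mask:
    v = read_volume(path)
    return Mask(data=(np.asarray(v.data) > 0).astype(np.uint8), spacing=v.spacing, origin=v.origin)


# ---------------------------------------------------------------------------
# mesh I/O (binary STL)
# ---------------------------------------------------------------------------

_EMPTY_STL = b"fibseg empty mesh".ljust(80, b"\0") + (0).to_bytes(4, "little")


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    if mesh.is_empty:
        warnings.warn(f"writing empty mesh to {path}", stacklevel=2)
        Path(path).write_bytes(_EMPTY_STL)
        return
    mesh.as_trimesh().export(str(path), file_type="stl")


def read_mesh(path: str | Path) -> SurfaceMesh:
    raw = Path(path).read_bytes()
    if raw == _EMPTY_STL or (len(raw) == 84 and raw[80:] == b"\0\0\0\0"):
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"cannot read mesh {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or tm.faces.shape[1] != 3:
        raise FormatError(f"{path}: not a triangle mesh")
    tm.merge_vertices()  # STL stores per-face vertices; restore shared ones
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# manifest I/O and cohort bookkeeping
# ---------------------------------------------------------------------------

_CSV_COLS = ["case_id", "image", "left_mask", "right_mask", "split"]


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    rows = [
        {
            "case_id": r.case_id,
            "image": r.image_path,
            "left_mask": r.left_mask_path or "",
            "right_mask": r.right_mask_path or "",
            "split": r.split,
        }
        for r in manifest.records
    ]
    pd.DataFrame(rows, columns=_CSV_COLS).to_csv(str(path), index=False)


def read_manifest(path: str | Path, provenance: str = "") -> Manifest:
    df = pd.read_csv(str(path), dtype=str, keep_default_na=False)
    missing = set(_CSV_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
    records = [
        CaseRecord(
            case_id=row.case_id,
            image_path=row.image,
            left_mask_path=row.left_mask or None,
            right_mask_path=row.right_mask or None,
            split=row.split or "unassigned",
        )
        for row in df.itertuples()
    ]
    return Manifest(records, provenance=provenance or str(path))


def filter_eligible(manifest: Manifest, approach_stage: str) -> Manifest:
    """Restrict a cohort to the samples usable by one pipeline stage.

    ``bilateral_step1`` needs joint ground truth, so only cases with both
    fibula masks survive.  ``unilateral_step1`` and ``step2`` consume each
    fibula as an individual sample (right fibulae are later mirrored to the
    left), so every available side becomes its own record with a
    ``<case>:<side>`` id.
    """
    if approach_stage not in ("bilateral_step1", "unilateral_step1", "step2"):
        raise ValueError(f"unknown stage {approach_stage!r}")
    if approach_stage == "bilateral_step1":
        records = [replace(r) for r in manifest.records if r.has_both]
    else:
        records = []
        for r in manifest.records:
            for side in r.available_sides:
                records.append(
                    CaseRecord(
                        case_id=f"{r.case_id}:{side}",
                        image_path=r.image_path,
                        left_mask_path=r.left_mask_path if side == "left" else None,
                        right_mask_path=r.right_mask_path if side == "right" else None,
                        split=r.split,
                    )
                )
    if not records:
        raise EmptyManifestError(f"no eligible samples for stage {approach_stage}")
    return Manifest(records, provenance=f"{manifest.provenance}|{approach_stage}")


def split_manifest(manifest: Manifest, ratio: tuple[int, int] = (9, 1), seed: int = 0) -> Manifest:
    """Assign train/val splits with a ``train:val`` integer ratio.

    The validation count is ``floor(n * val_fraction)`` but never below one
    case; the remainder trains.  Deterministic for a fixed seed.
    """
    n = len(manifest)
    if n < 2:
        raise ValueError(f"cannot split a manifest of {n} record(s)")
    tr, va = ratio
    if tr <= 0 or va <= 0:
        raise ValueError(f"ratio parts must be positive, got {ratio}")
    n_val = max(1, int(np.floor(n * va / (tr + va))))
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    records = [
        replace(r, split="val" if i in val_idx else "train")
        for i, r in enumerate(manifest.records)
    ]
    return Manifest(records, provenance=f"{manifest.provenance}|split{tr}:{va}/seed{seed}")
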