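"""Geometric and intensity plumbing shared by both segmentation pipelines.

Covers Hounsfield-unit normalization, fixed-grid resampling, mid-plane
splitting, left-right mirroring, and bounding-box crop/uncrop.  All physical
distances are in millimetres; voxel indices are 0-based and bounding-box
ranges are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .volume_io import AXIS_LR, Mask, ShapeError, Volume

HU_MIN = -1024.0
HU_MAX = 3071.0


class EmptyMaskError(ValueError):
    """A bounding box was requested for a mask with no foreground.

    This is the failure surface of a fragmented first-stage prediction: when
    the localization step misses a fibula entirely there is nothing to crop,
    and the pipeline must degrade gracefully instead of crashing.
    """


@dataclass(frozen=True)
class BBox:
    """Axis-aligned inclusive voxel-index box on a stated reference grid."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"bbox lo {self.lo} exceeds hi {self.hi}")
        if any(l < 0 for l in self.lo):
            raise ValueError(f"bbox lo {self.lo} below grid bounds")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l + 1 for l, h in zip(self.lo, self.hi))


def normalize_hu(volume: Volume) -> Volume:
    """Clip to the standard HU range and map linearly onto [0, 1].

    ``-1024 HU -> 0.0`` and ``+3071 HU -> 1.0``; values outside the range are
    clipped first.  Total function; masks should not be passed through it.
    """
    data = np.clip(np.asarray(volume.data, dtype=np.float32), HU_MIN, HU_MAX)
    data = (data - HU_MIN) / (HU_MAX - HU_MIN)
    return Volume(data=data, spacing=volume.spacing, origin=volume.origin)


def _nearest_indices(src: int, dst: int) -> np.ndarray:
    # voxel-center mapping: target voxel i covers source interval of width src/dst
    idx = np.floor((np.arange(dst) + 0.5) * src / dst).astype(np.intp)
    return np.clip(idx, 0, src - 1)


def resample(obj: Union[Volume, Mask], target_shape: tuple[int, int, int],
             interpolation: str | None = None) -> Union[Volume, Mask]:
    """Resample onto a fixed grid, preserving the physical extent.

    Images use trilinear interpolation, masks nearest-neighbour (so they stay
    binary); the default is chosen from the input type.  The output spacing is
    rescaled by ``old_shape / new_shape`` per axis.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ShapeError(f"invalid target shape {target_shape}")
    if interpolation is None:
        interpolation = "nearest" if isinstance(obj, Mask) else "trilinear"
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    src_shape = obj.shape
    new_spacing = tuple(sp * s / t for sp, s, t in zip(obj.spacing, src_shape, target_shape))
    if interpolation == "nearest":
        ix, iy, iz = (_nearest_indices(s, t) for s, t in zip(src_shape, target_shape))
        data = np.asarray(obj.data)[np.ix_(ix, iy, iz)]
        if isinstance(obj, Mask):
            return Mask(data=data.copy(), spacing=new_spacing, origin=obj.origin)
        return Volume(data=data.copy(), spacing=new_spacing, origin=obj.origin)

    coords = np.meshgrid(
        *[(np.arange(t) + 0.5) * s / t - 0.5 for s, t in zip(src_shape, target_shape)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(
        np.asarray(obj.data, dtype=np.float32), np.stack(coords), order=1, mode="nearest"
    )
    return Volume(data=data, spacing=new_spacing, origin=obj.origin)


def mirror_lr(obj: Union[Volume, Mask]) -> Union[Volume, Mask]:
    """Flip about the field-of-view mid-plane along the left-right grid axis.

    A pure grid flip with no interpolation; spacing is unchanged.  This
    mirrors about the image mid-plane, not the anatomical mid-sagittal plane.
    """
    data = np.flip(np.asarray(obj.data), axis=AXIS_LR).copy()
    cls = Mask if isinstance(obj, Mask) else Volume
    return cls(data=data, spacing=obj.spacing, origin=obj.origin)


def split_halves(obj: Union[Volume, Mask]) -> tuple[Union[Volume, Mask], Union[Volume, Mask]]:
    """Split at the mid-plane into (left, right) halves covering the grid.

    The left-right axis increases toward the patient's left, so the left half
    is the upper index block; on an odd axis it takes the extra column.  Each
    half keeps a physically consistent origin so the halves reassemble into
    the original volume exactly.
    """
    n = obj.shape[AXIS_LR]
    if n < 2:
        raise ShapeError("left-right axis must have size >= 2 to split")
    n_left = (n + 1) // 2
    cut = n - n_left
    data = np.asarray(obj.data)
    right = data[:cut]
    left = data[cut:]
    cls = Mask if isinstance(obj, Mask) else Volume
    left_origin = (obj.origin[0] + cut * obj.spacing[0], obj.origin[1], obj.origin[2])
    return (
        cls(data=left.copy(), spacing=obj.spacing, origin=left_origin),
        cls(data=right.copy(), spacing=obj.spacing, origin=obj.origin),
    )


def reassemble_halves(left: Union[Volume, Mask], right: Union[Volume, Mask]) -> Union[Volume, Mask]:
    data = np.concatenate([np.asarray(right.data), np.asarray(left.data)], axis=AXIS_LR)
    cls = Mask if isinstance(left, Mask) else Volume
    return cls(data=data, spacing=right.spacing, origin=right.origin)


def mask_bbox(mask: Mask, margin_mm: float = 0.0) -> BBox:
    """Tightest box around the foreground, expanded by a physical margin.

    The margin is converted to voxels per axis (rounded up) and the box is
    clipped to the grid.  An empty mask raises :class:`EmptyMaskError`, which
    callers must be able to catch: it is how a failed localization surfaces.
    """
    fg = np.asarray(mask.data) > 0
    if not fg.any():
        raise EmptyMaskError("cannot compute bounding box of an empty mask")
    lo, hi = [], []
    for ax in range(3):
        proj = fg.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        m = int(np.ceil(margin_mm / mask.spacing[ax])) if margin_mm > 0 else 0
        lo.append(max(0, int(idx[0]) - m))
        hi.append(min(fg.shape[ax] - 1, int(idx[-1]) + m))
    return BBox(lo=tuple(lo), hi=tuple(hi), margin_mm=margin_mm)


def crop(obj: Union[Volume, Mask], bbox: BBox) -> Union[Volume, Mask]:
    if any(h >= s for h, s in zip(bbox.hi, obj.shape)):
        raise IndexError(f"bbox {bbox.lo}-{bbox.hi} exceeds grid {obj.shape}")
    data = np.asarray(obj.data)[bbox.slices].copy()
    origin = tuple(o + l * sp for o, l, sp in zip(obj.origin, bbox.lo, obj.spacing))
    cls = Mask if isinstance(obj, Mask) else Volume
    return cls(data=data, spacing=obj.spacing, origin=origin)


def uncrop(mask: Mask, bbox: BBox, full_shape: tuple[int, int, int],
           origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> Mask:
    """Place a cropped mask back on the original grid, zero outside the box."""
    if any(h >= s for h, s in zip(bbox.hi, full_shape)):
        raise IndexError(f"bbox {bbox.lo}-{bbox.hi} exceeds grid {full_shape}")
    if tuple(mask.shape) != tuple(bbox.shape):
        raise ShapeError(f"mask shape {mask.shape} does not match bbox extent {bbox.shape}")
    full = np.zeros(full_shape, dtype=np.uint8)
    full[bbox.slices] = mask.data
    return Mask(data=full, spacing=mask.spacing, origin=origin)
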