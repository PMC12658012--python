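"""Segmentation evaluation: Dice score, surface distances, and the
transplant-specific ROI restriction.

The Dice score compares two voxel sets A (ground truth) and B (prediction):
``DS = 2|A ∩ B| / (|A| + |B|)``.  The surface metrics operate on boundary
voxel centers in physical millimetres: the Average Surface Distance (ASD)
is the mean of all directed nearest-neighbour distances pooled over both
directions, and the 95% Hausdorff Distance (HD95) the 95th percentile of
the same pooled multiset (linear interpolation between order statistics).

Because only the central part of the fibula is transplanted — roughly 7 cm
at each end stay in the leg to keep the knee and ankle stable — the ROI
variants first remove a ``crop_mm`` band from the top and bottom of the
*ground-truth* z-extent and apply the identical window to both masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import AXIS_IS, Mask, ShapeError

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricReport:
    """Whole-bone and ROI-restricted metrics for one ground-truth/prediction pair."""

    ds: float
    asd: float | None
    hd95: float | None
    roi_ds: float | None
    roi_asd: float | None
    roi_hd95: float | None
    surface_valid: bool
    roi_valid: bool

    def as_row(self) -> dict:
        return {
            "DS": self.ds,
            "ASD_mm": self.asd,
            "HD95_mm": self.hd95,
            "ROI_DS": self.roi_ds,
            "ROI_ASD_mm": self.roi_asd,
            "ROI_HD95_mm": self.roi_hd95,
        }


def _check_same_grid(a: Mask, b: Mask) -> None:
    if a.shape != b.shape:
        raise ShapeError(f"masks on different grids: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ShapeError(f"masks with different spacings: {a.spacing} vs {b.spacing}")


def dice(a: Mask, b: Mask) -> float:
    """Dice overlap of two masks on the same grid; dice(empty, empty) = 1."""
    _check_same_grid(a, b)
    na, nb = a.count(), b.count()
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: Mask) -> np.ndarray:
    """Physical-mm centers of foreground voxels with a 6-connected background
    neighbour; voxels on the grid border count the outside as background."""
    fg = np.asarray(mask.data, dtype=bool)
    if not fg.any():
        raise ValueError("empty mask has no surface")
    interior = ndimage.binary_erosion(fg, structure=_SIX_CONN, border_value=0)
    idx = np.argwhere(fg & ~interior).astype(np.float64)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def _pooled_surface_distances(a: Mask, b: Mask) -> np.ndarray:
    pa, pb = surface_voxels(a), surface_voxels(b)
    d_ab = cKDTree(pb).query(pa, workers=1)[0]
    d_ba = cKDTree(pa).query(pb, workers=1)[0]
    return np.concatenate([d_ab, d_ba])


def asd(a: Mask, b: Mask) -> float:
    """Symmetric Average Surface Distance in mm (pooled over both directions)."""
    _check_same_grid(a, b)
    return float(_pooled_surface_distances(a, b).mean())


def hd95(a: Mask, b: Mask, q: float = 95.0) -> float:
    """95th percentile of the pooled directed surface distances, in mm."""
    _check_same_grid(a, b)
    return float(np.percentile(_pooled_surface_distances(a, b), q))


def roi_restrict(gt: Mask, pred: Mask, crop_mm: float = 70.0) -> tuple[Mask, Mask]:
    """Remove ``crop_mm`` from the top and bottom of the bone for evaluation.

    The z-window ``[z_min(gt) + crop_mm, z_max(gt) - crop_mm]`` is computed
    once from the ground-truth extent along the inferior-superior axis and
    applied to both masks.  If the ground truth is shorter than twice the
    crop the returned masks are empty (callers flag the ROI as invalid).
    """
    _check_same_grid(gt, pred)
    if gt.count() == 0:
        raise ValueError("ROI window requires a non-empty ground truth")
    if crop_mm < 0:
        raise ValueError("crop_mm must be >= 0")
    sz = gt.spacing[AXIS_IS]
    z_any = np.asarray(gt.data, bool).any(axis=(0, 1))
    z_idx = np.nonzero(z_any)[0]
    z_lo_mm = z_idx[0] * sz + crop_mm
    z_hi_mm = z_idx[-1] * sz - crop_mm
    nz = gt.shape[AXIS_IS]
    window = np.zeros(gt.shape, dtype=np.uint8)
    if crop_mm == 0 or z_hi_mm - z_lo_mm > 1e-9:
        # a bone no longer than twice the crop leaves no usable window
        keep = (np.arange(nz) * sz >= z_lo_mm - 1e-9) & (np.arange(nz) * sz <= z_hi_mm + 1e-9)
        window[:, :, keep] = 1
    return (
        Mask(gt.data * window, gt.spacing, gt.origin),
        Mask(pred.data * window, pred.spacing, pred.origin),
    )


def evaluate_pair(gt: Mask, pred: Mask, crop_mm: float = 70.0) -> MetricReport:
    """All six metrics for one pair; distance metrics are flagged invalid
    (``None``) whenever either side is empty."""
    _check_same_grid(gt, pred)
    ds = dice(gt, pred)
    surf_ok = gt.count() > 0 and pred.count() > 0
    a = asd(gt, pred) if surf_ok else None
    h = hd95(gt, pred) if surf_ok else None

    roi_ds = roi_asd = roi_hd95 = None
    roi_ok = False
    if gt.count() > 0:
        gt_r, pred_r = roi_restrict(gt, pred, crop_mm)
        if gt_r.count() > 0:
            roi_ds = dice(gt_r, pred_r)
            if pred_r.count() > 0:
                roi_ok = True
                roi_asd = asd(gt_r, pred_r)
                roi_hd95 = hd95(gt_r, pred_r)
    return MetricReport(
        ds=ds, asd=a, hd95=h,
        roi_ds=roi_ds, roi_asd=roi_asd, roi_hd95=roi_hd95,
        surface_valid=surf_ok, roi_valid=roi_ok,
    )
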