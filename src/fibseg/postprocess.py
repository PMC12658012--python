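"""From probability volumes to clean masks and surgical-quality meshes.

The chain is: binarize -> connected-component filtering -> binary erosion ->
Gaussian smoothing -> marching cubes.  Component analysis runs on the voxel
masks (cheaper and equivalent for size ranking and left/right labeling);
meshes are emitted from the smoothed field so the exported surfaces are the
deliverable a surgical planner would load.
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import AXIS_LR, Mask, SurfaceMesh, Volume

_BOX_26 = np.ones((3, 3, 3), dtype=bool)


class EmptySurfaceError(ValueError):
    """Marching cubes found no crossing of the iso level."""


class LabelingError(ValueError):
    """Left/right assignment is ambiguous (equal lateral centroids)."""


def binarize(prob_volume: Volume, threshold: float = 0.5) -> Mask:
    """Foreground where probability >= threshold."""
    data = (np.asarray(prob_volume.data) >= threshold).astype(np.uint8)
    return Mask(data, prob_volume.spacing, prob_volume.origin)


def erode(mask: Mask, element: np.ndarray = _BOX_26, iterations: int = 1) -> Mask:
    """Binary erosion; default element is the 3x3x3 box, one iteration."""
    if iterations < 1:
        return Mask(mask.data.copy(), mask.spacing, mask.origin)
    data = ndimage.binary_erosion(
        mask.data.astype(bool), structure=element, iterations=iterations, border_value=0
    )
    return Mask(data.astype(np.uint8), mask.spacing, mask.origin)


def smooth(mask: Mask, sigma_mm: float | None = None, sigma_vox: float = 1.0) -> Volume:
    """Gaussian smoothing of a binary mask into a [0, 1] scalar field.

    ``sigma_mm`` is converted per axis with the voxel spacing (anisotropy
    aware); if omitted, an isotropic ``sigma_vox`` voxels is used.  Sigma 0
    returns the mask unchanged as floats.
    """
    data = mask.data.astype(np.float32)
    if sigma_mm is not None:
        if sigma_mm < 0:
            raise ValueError("sigma_mm must be >= 0")
        sigmas = [sigma_mm / s for s in mask.spacing]
    else:
        sigmas = [sigma_vox] * 3
    if all(s == 0 for s in sigmas):
        return Volume(data, mask.spacing, mask.origin)
    field = ndimage.gaussian_filter(data, sigma=sigmas, mode="constant", cval=0.0)
    return Volume(field, mask.spacing, mask.origin)


def extract_mesh(scalar_field: Volume, iso_level: float = 0.5) -> SurfaceMesh:
    """Marching-cubes iso-surface in physical mm coordinates.

    The field is zero-padded by one voxel first so that blobs touching the
    grid border still produce closed (watertight) surfaces.
    """
    data = np.asarray(scalar_field.data, dtype=np.float32)
    if not (data.min() < iso_level < data.max()):
        raise EmptySurfaceError(
            f"field range [{data.min():.3g}, {data.max():.3g}] does not straddle "
            f"iso level {iso_level}"
        )
    padded = np.pad(data, 1, mode="constant", constant_values=0.0)
    verts, faces, _, _ = measure.marching_cubes(
        padded, level=iso_level, spacing=scalar_field.spacing
    )
    verts = verts - np.asarray(scalar_field.spacing)  # undo the pad offset
    verts = verts + np.asarray(scalar_field.origin)
    return SurfaceMesh(verts, faces)


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume in mm^3 (divergence theorem on the triangle fan)."""
    v = mesh.vertices
    f = mesh.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _component_masks(mask: Mask) -> list[Mask]:
    labels, n = ndimage.label(mask.data, structure=_BOX_26)
    return [
        Mask((labels == i).astype(np.uint8), mask.spacing, mask.origin)
        for i in range(1, n + 1)
    ]


def _size(c: Union[Mask, SurfaceMesh]) -> float:
    return float(c.count()) if isinstance(c, Mask) else mesh_volume(c)


def _lr_centroid(c: Union[Mask, SurfaceMesh]) -> float:
    if isinstance(c, Mask):
        idx = np.argwhere(c.data > 0)
        return float(idx[:, AXIS_LR].mean() * c.spacing[AXIS_LR] + c.origin[AXIS_LR])
    return float(c.vertices[:, AXIS_LR].mean())


def keep_largest_components(obj, k: int = 2, min_fraction: float = 0.0):
    """The ``k`` largest connected components in descending size order.

    Accepts a :class:`Mask` (components by 26-connectivity, size in voxels)
    or a sequence of meshes (size by enclosed volume).  Components smaller
    than ``min_fraction`` of the largest are discarded as debris *before*
    counting.  Returns ``(components, shortfall)`` where ``shortfall`` is
    True when fewer than ``k`` components survive — the caller decides how
    to degrade; nothing is ever silently padded.  Ties in size break by
    lateral centroid, ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(obj, Mask):
        comps = _component_masks(obj)
    else:
        comps = list(obj)
    if not comps:
        return [], True
    sizes = np.array([_size(c) for c in comps])
    if min_fraction > 0:
        keep = sizes >= min_fraction * sizes.max()
        comps = [c for c, kp in zip(comps, keep) if kp]
        sizes = sizes[keep]
    order = sorted(range(len(comps)), key=lambda i: (-sizes[i], _lr_centroid(comps[i])))
    top = [comps[i] for i in order[:k]]
    return top, len(top) < k


def label_left_right(two_components: Sequence) -> dict:
    """Assign left/right by lateral centroid under the grid convention
    (index increasing toward the patient's left => greater centroid = left)."""
    if len(two_components) != 2:
        raise ValueError(f"need exactly two components, got {len(two_components)}")
    c0, c1 = two_components
    x0, x1 = _lr_centroid(c0), _lr_centroid(c1)
    if x0 == x1:
        raise LabelingError("components have identical lateral centroids")
    return {"left": c0 if x0 > x1 else c1, "right": c0 if x0 < x1 else c1}


def mask_to_mesh(mask: Mask, erode_iterations: int = 1,
                 sigma_vox: float = 1.0, iso_level: float = 0.5) -> SurfaceMesh:
    """The full erode -> smooth -> marching-cubes chain for one mask."""
    if mask.count() == 0:
        raise EmptySurfaceError("cannot mesh an empty mask")
    m = erode(mask, iterations=erode_iterations)
    if m.count() == 0:  # erosion ate a very thin structure; fall back
        m = mask
    field = smooth(m, sigma_vox=sigma_vox)
    if not (field.data.min() < iso_level < field.data.max()):
        # structure thinner than the smoothing kernel: mesh the raw voxels
        field = smooth(m, sigma_mm=0.0)
    return extract_mesh(field, iso_level=iso_level)
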