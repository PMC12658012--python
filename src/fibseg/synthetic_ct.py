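"""Seeded lower-limb CT phantoms with paired fibula ground truth.

The clinical cohorts this package targets cannot be redistributed, so the
benchmark data are generated: each phantom holds two soft-tissue "legs" on
opposite sides of the field-of-view mid-plane, and per leg one thick
straight distractor bone (tibia) and one thin, slightly bowed target bone
(fibula) whose proximal and distal ends carry spherical bulges emulating
the fibular head and the lateral malleolus.  Intensities follow CT
Hounsfield conventions (air / soft tissue / trabecular / cortical bone)
with optional additive Gaussian noise.

Geometry is defined analytically (a low-order polynomial centerline
rasterized by distance thresholding), so the expected bone volume has a
closed form that tests can check the rasterization against.  Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .volume_io import (
    AXIS_IS,
    AXIS_LR,
    CaseRecord,
    EmptyManifestError,
    Manifest,
    Mask,
    Volume,
    write_manifest,
    write_mask,
    write_volume,
)

HU_CLIP = (-1024.0, 3071.0)


class GeometryError(ValueError):
    """The requested anatomy does not fit the requested grid."""


@dataclass(frozen=True)
class PhantomParams:
    """All knobs of one phantom; defaults are proportioned like a
    lower-extremity CT field of view at coarse desk-test resolution."""

    grid_shape: tuple[int, int, int] = (64, 64, 160)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.5)  # mm
    leg_center_offset_mm: float = 32.0     # leg axis distance from the mid-plane
    leg_radius_mm: float = 26.0            # soft-tissue cylinder
    tibia_radius_mm: float = 12.0
    tibia_offset_mm: tuple[float, float] = (-10.0, -8.0)   # (lateral, AP) from leg axis
    fibula_radius_mm: float = 5.0          # shaft
    fibula_offset_mm: tuple[float, float] = (14.0, 6.0)    # (lateral, AP) from leg axis
    fibula_head_radius_mm: float = 9.0     # proximal bulge
    fibula_ankle_radius_mm: float = 8.0    # distal bulge
    bow_mm: float = 4.0                    # lateral centerline bow amplitude
    bone_z_fraction: tuple[float, float] = (0.05, 0.95)
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_trabecular: float = 800.0
    hu_cortical: float = 1200.0
    noise_sd: float = 20.0                 # HU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fibula_radius_mm >= self.tibia_radius_mm:
            raise ValueError("fibula must be thinner than the tibia")
        if self.leg_center_offset_mm <= 0:
            raise ValueError("leg centers must sit strictly off the mid-plane")
        for hu in (self.hu_air, self.hu_soft, self.hu_trabecular, self.hu_cortical):
            if not HU_CLIP[0] <= hu <= HU_CLIP[1]:
                raise ValueError(f"HU level {hu} outside the representable range")
        half_extent = self.grid_shape[AXIS_LR] * self.spacing[AXIS_LR] / 2.0
        reach = self.leg_center_offset_mm + self.leg_radius_mm
        if reach > half_extent:
            raise GeometryError(
                f"leg (offset {self.leg_center_offset_mm} + radius {self.leg_radius_mm} mm) "
                f"does not fit the {half_extent:.0f} mm half field of view"
            )

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))

    def bone_z_range_mm(self) -> tuple[float, float]:
        lz = self.extent_mm[AXIS_IS]
        return self.bone_z_fraction[0] * lz, self.bone_z_fraction[1] * lz

    def analytic_fibula_volume_mm3(self) -> float:
        """Closed-form shaft + bulge volume for the rasterization oracle.

        Shaft: a tube of radius r along the bowed centerline (arc length of
        the quadratic bow); bulges: two spheres, each minus the cylinder
        segment already inside the shaft.
        """
        z0, z1 = self.bone_z_range_mm()
        length = z1 - z0
        # arc length of x(z) = 4*b*t*(1-t), t in [0,1] (quadratic bow)
        t = np.linspace(0.0, 1.0, 2049)
        dxdt = 4.0 * self.bow_mm * (1.0 - 2.0 * t)
        arc = np.trapezoid(np.sqrt(length ** 2 + dxdt ** 2), t)
        r = self.fibula_radius_mm
        shaft = np.pi * r ** 2 * arc
        bulges = 0.0
        for rb in (self.fibula_head_radius_mm, self.fibula_ankle_radius_mm):
            cyl_in_sphere = np.pi * r ** 2 * rb  # shaft segment inside one hemisphere
            bulges += 4.0 / 3.0 * np.pi * rb ** 3 - cyl_in_sphere
        return float(shaft + bulges)


@dataclass
class PhantomCase:
    image: Volume
    left_fibula: Mask
    right_fibula: Mask
    params: PhantomParams


def _grids(params: PhantomParams):
    x = np.arange(params.grid_shape[0]) * params.spacing[0]
    y = np.arange(params.grid_shape[1]) * params.spacing[1]
    z = np.arange(params.grid_shape[2]) * params.spacing[2]
    return np.meshgrid(x, y, z, indexing="ij")


def _fibula_mask(params: PhantomParams, leg_x: float, lateral_sign: float,
                 X, Y, Z) -> np.ndarray:
    z0, z1 = params.bone_z_range_mm()
    fx = leg_x + lateral_sign * params.fibula_offset_mm[0]
    fy = params.extent_mm[1] / 2.0 + params.fibula_offset_mm[1]
    t = np.clip((Z - z0) / (z1 - z0), 0.0, 1.0)
    cx = fx + lateral_sign * 4.0 * params.bow_mm * t * (1.0 - t)
    in_z = (Z >= z0) & (Z <= z1)
    shaft = in_z & ((X - cx) ** 2 + (Y - fy) ** 2 <= params.fibula_radius_mm ** 2)
    head = ((X - fx) ** 2 + (Y - fy) ** 2 + (Z - z1) ** 2
            <= params.fibula_head_radius_mm ** 2)
    ankle = ((X - fx) ** 2 + (Y - fy) ** 2 + (Z - z0) ** 2
             <= params.fibula_ankle_radius_mm ** 2)
    return shaft | head | ankle


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """One two-leg phantom with left/right fibula ground-truth masks."""
    X, Y, Z = _grids(params)
    ex, ey, _ = params.extent_mm
    mid = ex / 2.0
    yc = ey / 2.0
    z0, z1 = params.bone_z_range_mm()
    in_z = (Z >= z0) & (Z <= z1)

    image = np.full(params.grid_shape, params.hu_air, dtype=np.float32)
    masks = {}
    # LR axis index increases toward the patient's left: the left leg lives
    # at x > mid-plane, the right leg mirrored below it.
    for side, sign in (("left", +1.0), ("right", -1.0)):
        leg_x = mid + sign * params.leg_center_offset_mm
        leg = (X - leg_x) ** 2 + (Y - yc) ** 2 <= params.leg_radius_mm ** 2
        image[leg] = params.hu_soft
        tx = leg_x + sign * params.tibia_offset_mm[0]
        ty = yc + params.tibia_offset_mm[1]
        tib = in_z & ((X - tx) ** 2 + (Y - ty) ** 2 <= params.tibia_radius_mm ** 2)
        core = in_z & ((X - tx) ** 2 + (Y - ty) ** 2
                       <= max(params.tibia_radius_mm - 4.0, 0.0) ** 2)
        image[tib] = params.hu_cortical
        image[core] = params.hu_trabecular
        fib = _fibula_mask(params, leg_x, sign, X, Y, Z)
        image[fib] = params.hu_cortical
        masks[side] = fib.astype(np.uint8)

    if (masks["left"] & masks["right"]).any():
        raise GeometryError("left and right fibulae overlap; widen the leg offsets")

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape).astype(np.float32)
    image = np.clip(image, *HU_CLIP)

    vol = Volume(image, params.spacing)
    return PhantomCase(
        image=vol,
        left_fibula=Mask(masks["left"], params.spacing),
        right_fibula=Mask(masks["right"], params.spacing),
        params=params,
    )


def fragment_fibula(case: PhantomCase, side: str = "right",
                    keep_slices: int = 4, gap_slices: int = 12) -> PhantomCase:
    """Break one fibula into short disconnected pieces (a hard localization case).

    Periodic z-bands of the bone are replaced by soft tissue in the image and
    removed from the ground truth, leaving fragments too small to pass a
    size-based component filter.  This reproduces the failure surface where a
    coarse first stage cannot see one fibula as a continuous bone.
    """
    mask = case.left_fibula if side == "left" else case.right_fibula
    frag = mask.data.copy()
    image = case.image.data.copy()
    nz = frag.shape[AXIS_IS]
    period = keep_slices + gap_slices
    for z in range(nz):
        if (z % period) >= keep_slices:
            removed = frag[:, :, z] > 0
            image[:, :, z][removed] = case.params.hu_soft
            frag[:, :, z] = 0
    new = PhantomCase(
        image=Volume(image, case.image.spacing, case.image.origin),
        left_fibula=case.left_fibula,
        right_fibula=case.right_fibula,
        params=case.params,
    )
    if side == "left":
        new.left_fibula = Mask(frag, mask.spacing, mask.origin)
    else:
        new.right_fibula = Mask(frag, mask.spacing, mask.origin)
    return new


def sample_params(base: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-subject anatomical variability around a base parameterization.

    Leg position, bone radii, lateral bow and bone span are jittered within
    plausible ranges so that no two cohort members share the same geometry —
    without this, networks can memorize absolute voxel positions instead of
    learning appearance.
    """
    return replace(
        base,
        leg_center_offset_mm=base.leg_center_offset_mm + rng.uniform(-3.0, 3.0),
        fibula_offset_mm=(base.fibula_offset_mm[0] + rng.uniform(-2.0, 2.0),
                          base.fibula_offset_mm[1] + rng.uniform(-3.0, 3.0)),
        fibula_radius_mm=float(rng.uniform(4.0, 6.0)),
        fibula_head_radius_mm=base.fibula_head_radius_mm + rng.uniform(-1.5, 1.5),
        fibula_ankle_radius_mm=base.fibula_ankle_radius_mm + rng.uniform(-1.5, 1.5),
        bow_mm=float(rng.uniform(2.0, 6.0)),
        tibia_radius_mm=base.tibia_radius_mm + rng.uniform(-2.0, 2.0),
        bone_z_fraction=(float(rng.uniform(0.04, 0.09)), float(rng.uniform(0.91, 0.96))),
    )


def generate_cohort(n_right_only: int, n_left_only: int, n_both: int,
                    params: PhantomParams, seed: int, out_dir: str | Path,
                    split: str = "unassigned", vary: bool = True) -> Manifest:
    """Write a phantom cohort with the requested laterality profile.

    Every case gets its own seed derived from the master seed and (unless
    ``vary=False``) its own anatomy drawn by :func:`sample_params`; only the
    requested ground-truth sides are written and referenced — emulating
    cohorts in which not every patient has both bones segmented.
    """
    counts = (n_right_only, n_left_only, n_both)
    if any(c < 0 for c in counts):
        raise ValueError("cohort counts must be non-negative")
    if sum(counts) == 0:
        raise EmptyManifestError("cohort with all counts zero")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=sum(counts))

    profiles = (
        [("right",)] * n_right_only + [("left",)] * n_left_only
        + [("left", "right")] * n_both
    )
    records = []
    for i, sides in enumerate(profiles):
        cid = f"case{i:03d}"
        p = replace(params, seed=int(case_seeds[i]))
        if vary:
            p = sample_params(p, np.random.default_rng(int(case_seeds[i])))
        case = generate_phantom(p)
        img_path = out_dir / f"{cid}_ct.nii.gz"
        write_volume(case.image, img_path)
        paths = {"left": None, "right": None}
        for s in sides:
            mp = out_dir / f"{cid}_{s}_fibula.nii.gz"
            write_mask(case.left_fibula if s == "left" else case.right_fibula, mp)
            paths[s] = str(mp)
        records.append(CaseRecord(cid, str(img_path), paths["left"], paths["right"], split))
    manifest = Manifest(records, provenance=f"synthetic:seed={seed}")
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
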