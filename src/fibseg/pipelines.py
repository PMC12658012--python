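"""End-to-end orchestration of the two-stage segmentation variants.

Both variants share the same idea: a coarse **localization** stage finds the
fibulae in a heavily down-sampled view, the image is cropped to a bounding
box around each detection, and a **refinement** stage segments the bone at
high relative resolution inside the crop.  Right fibulae are mirrored about
the field-of-view mid-plane before refinement so one network serves both
sides, and the prediction is mirrored back afterwards.

* **bilateral** — stage 1 sees the whole down-sampled CT and must find both
  fibulae at once; training it needs cases with both sides annotated.
* **unilateral** — the CT is split at the mid-plane, the right half is
  mirrored, and one stage-1 network runs on each half independently; every
  annotated fibula is usable for training and a failure on one side cannot
  take the other down.

A localization that does not yield the expected number of bones degrades
gracefully: the available side is emitted and the missing one is flagged
(``shortfall`` when component filtering came up short, ``empty`` when a
stage produced no foreground).  Statuses are machine-readable; the pipeline
never crashes on these cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import unet3d
from .metrics import evaluate_pair
from .postprocess import (
    binarize,
    keep_largest_components,
    label_left_right,
    mask_to_mesh,
)
from .preprocess import (
    BBox,
    crop,
    mask_bbox,
    mirror_lr,
    normalize_hu,
    resample,
    split_halves,
    uncrop,
)
from .unet3d import NetworkSpec, TrainConfig, WeightState, expansion_transfer
from .volume_io import (
    AXIS_LR,
    Manifest,
    Mask,
    SurfaceMesh,
    Volume,
    filter_eligible,
    read_mask,
    read_volume,
)

SIDES = ("left", "right")

#: resolutions used by the reference pipelines on clinical-scale data
BILATERAL_STAGE1_SHAPE = (144, 144, 288)
UNILATERAL_STAGE1_SHAPE = (96, 192, 320)
STAGE2_SHAPE = (80, 80, 960)


@dataclass
class PipelineConfig:
    approach: str = "bilateral"
    stage1_shape: tuple[int, int, int] = BILATERAL_STAGE1_SHAPE
    stage2_shape: tuple[int, int, int] = STAGE2_SHAPE
    bbox_margin_mm: float = 5.0
    threshold: float = 0.5
    min_component_fraction: float = 0.1
    erode_iterations: int = 1
    smooth_sigma_vox: float = 1.0
    iso_level: float = 0.5
    crop_mm: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.approach not in ("bilateral", "unilateral"):
            raise ValueError(f"unknown approach {self.approach!r}")
        for shape in (self.stage1_shape, self.stage2_shape):
            unet3d.validate_input_shape(shape)

    @classmethod
    def bilateral(cls, **kw) -> "PipelineConfig":
        return cls(approach="bilateral", stage1_shape=BILATERAL_STAGE1_SHAPE, **kw)

    @classmethod
    def unilateral(cls, **kw) -> "PipelineConfig":
        return cls(approach="unilateral", stage1_shape=UNILATERAL_STAGE1_SHAPE, **kw)

    @classmethod
    def scaled(cls, approach: str, **kw) -> "PipelineConfig":
        """Desk-scale resolutions for phantom cohorts (see docs/methods.md)."""
        stage1 = (32, 32, 48) if approach == "bilateral" else (32, 48, 48)
        kw.setdefault("stage2_shape", (32, 32, 64))
        # margin proportionate to the coarse phantom voxels (~5 voxels), as the
        # clinical 5 mm default is at sub-millimetre spacing
        kw.setdefault("bbox_margin_mm", 12.0)
        return cls(approach=approach, stage1_shape=stage1, **kw)


@dataclass
class SegmentationResult:
    masks: dict[str, Optional[Mask]] = field(default_factory=dict)
    meshes: dict[str, Optional[SurfaceMesh]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)
    bboxes: dict[str, Optional[BBox]] = field(default_factory=dict)

    @property
    def ok_sides(self) -> list[str]:
        return [s for s in SIDES if self.status.get(s) == "ok"]


def _stage1_mask(weights: WeightState, norm: Volume, shape, threshold: float) -> Mask:
    s1_in = resample(norm, shape)
    prob = unet3d.forward(weights, s1_in.data)
    # upsample the probability field (trilinear) before thresholding: far less
    # quantized than upsampling an already-binarized coarse mask
    full = resample(Volume(prob, s1_in.spacing, s1_in.origin), norm.shape, "trilinear")
    return binarize(Volume(full.data, norm.spacing, norm.origin), threshold)


def _second_stage(norm: Volume, bbox: BBox, side: str, weights2: WeightState,
                  cfg: PipelineConfig) -> Optional[Mask]:
    """Crop, (mirror), refine, (re-mirror), uncrop. None if nothing predicted."""
    sub = crop(norm, bbox)
    if side == "right":
        sub = mirror_lr(sub)
    x = resample(sub, cfg.stage2_shape)
    prob = unet3d.forward(weights2, x.data)
    back = resample(Volume(prob, x.spacing, x.origin), sub.shape, "trilinear")
    pred = binarize(Volume(back.data, norm.spacing), cfg.threshold)
    comps, _ = keep_largest_components(pred, k=1)
    if not comps:
        return None
    out = comps[0]
    if side == "right":
        out = mirror_lr(out)
    return uncrop(Mask(out.data, norm.spacing), bbox, norm.shape, origin=norm.origin)


def _finalize_side(result: SegmentationResult, side: str, mask: Optional[Mask],
                   cfg: PipelineConfig) -> None:
    if mask is None or mask.count() == 0:
        result.masks[side] = None
        result.meshes[side] = None
        result.status[side] = "empty"
        return
    result.masks[side] = mask
    result.meshes[side] = mask_to_mesh(
        mask, erode_iterations=cfg.erode_iterations,
        sigma_vox=cfg.smooth_sigma_vox, iso_level=cfg.iso_level,
    )
    result.status[side] = "ok"


def _mid_plane_mm(volume: Volume) -> float:
    n = volume.shape[AXIS_LR]
    return volume.origin[AXIS_LR] + (n - 1) / 2.0 * volume.spacing[AXIS_LR]


def segment_bilateral(ct: Volume, weights1: WeightState, weights2: WeightState,
                      cfg: Optional[PipelineConfig] = None) -> SegmentationResult:
    """Joint localization of both fibulae, then per-side refinement.

    After thresholding the coarse prediction, the two largest connected
    components (debris below ``min_component_fraction`` of the largest is
    discarded first) are taken to be the fibulae and labeled left/right by
    lateral centroid.  Fewer than two surviving components is the known
    fragile mode of this variant: the found side is still refined, the other
    is flagged ``shortfall``.
    """
    cfg = cfg or PipelineConfig.bilateral()
    result = SegmentationResult()
    norm = normalize_hu(ct)
    m1 = _stage1_mask(weights1, norm, cfg.stage1_shape, cfg.threshold)
    comps, shortfall = keep_largest_components(
        m1, k=2, min_fraction=cfg.min_component_fraction
    )
    assigned: dict[str, Mask] = {}
    if len(comps) == 2:
        assigned = label_left_right(comps)
    elif len(comps) == 1:
        from .postprocess import _lr_centroid  # centroid rule, shared
        side = "left" if _lr_centroid(comps[0]) > _mid_plane_mm(ct) else "right"
        assigned = {side: comps[0]}
        result.status[SIDES[0] if side == SIDES[1] else SIDES[1]] = "shortfall"
    else:
        result.status = {s: "empty" for s in SIDES}

    for side in SIDES:
        if side not in assigned:
            result.status.setdefault(side, "shortfall")
            result.masks[side] = None
            result.meshes[side] = None
            result.bboxes[side] = None
            continue
        bbox = mask_bbox(assigned[side], cfg.bbox_margin_mm)
        result.bboxes[side] = bbox
        _finalize_side(result, side, _second_stage(norm, bbox, side, weights2, cfg), cfg)
    return result


def segment_unilateral(ct: Volume, weights1: WeightState, weights2: WeightState,
                       cfg: Optional[PipelineConfig] = None) -> SegmentationResult:
    """Split at the mid-plane, mirror the right half, localize per half.

    One stage-1 network (trained on left-side views) runs on both halves; a
    failure on one half only flags that side.  Refinement then proceeds on
    the full grid exactly as in the bilateral variant.
    """
    cfg = cfg or PipelineConfig.unilateral()
    result = SegmentationResult()
    norm = normalize_hu(ct)
    left_half, right_half = split_halves(norm)
    cut = ct.shape[AXIS_LR] - left_half.shape[AXIS_LR]

    for side in SIDES:
        half = left_half if side == "left" else mirror_lr(right_half)
        m1 = _stage1_mask(weights1, half, cfg.stage1_shape, cfg.threshold)
        comps, _ = keep_largest_components(m1, k=1)
        if not comps:
            result.status[side] = "empty"
            result.masks[side] = None
            result.meshes[side] = None
            result.bboxes[side] = None
            continue
        bb = mask_bbox(comps[0], cfg.bbox_margin_mm)
        if side == "left":
            lo0, hi0 = cut + bb.lo[AXIS_LR], cut + bb.hi[AXIS_LR]
        else:
            n_r = right_half.shape[AXIS_LR]  # mirrored index i <-> n_r - 1 - i
            lo0, hi0 = n_r - 1 - bb.hi[AXIS_LR], n_r - 1 - bb.lo[AXIS_LR]
        bbox = BBox((lo0, bb.lo[1], bb.lo[2]), (hi0, bb.hi[1], bb.hi[2]),
                    margin_mm=cfg.bbox_margin_mm)
        result.bboxes[side] = bbox
        _finalize_side(result, side, _second_stage(norm, bbox, side, weights2, cfg), cfg)
    return result


def segment(ct: Volume, weights1: WeightState, weights2: WeightState,
            cfg: PipelineConfig) -> SegmentationResult:
    fn = segment_bilateral if cfg.approach == "bilateral" else segment_unilateral
    return fn(ct, weights1, weights2, cfg)


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------

def _load_case(record):
    image = read_volume(record.image_path)
    masks = {s: read_mask(record.mask_path(s)) for s in record.available_sides}
    return image, masks


def _resample_target(mask: Mask, shape) -> np.ndarray:
    """Antialiased mask downsampling: trilinear on floats, then majority vote.
    Cleaner coarse labels than nearest-neighbour picking for thin bones."""
    f = resample(Volume(mask.data.astype(np.float32), mask.spacing, mask.origin),
                 shape, "trilinear")
    return (f.data >= 0.5).astype(np.float32)


def _jittered_bbox(mask: Mask, cfg: PipelineConfig, rng) -> "BBox":
    """GT box with per-face padding jitter.

    At inference the crop box comes from the localization stage and carries a
    few voxels of slop; training crops must show the same variability or the
    refinement net learns the bone's position inside the box as a shortcut.
    """
    tight = mask_bbox(mask, 0.0)
    max_pad = [max(2, int(np.ceil(2 * cfg.bbox_margin_mm / s))) for s in mask.spacing]
    lo, hi = [], []
    for ax in range(3):
        lo.append(max(0, tight.lo[ax] - int(rng.integers(1, max_pad[ax] + 1))))
        hi.append(min(mask.shape[ax] - 1, tight.hi[ax] + int(rng.integers(1, max_pad[ax] + 1))))
    return BBox(tuple(lo), tuple(hi), margin_mm=cfg.bbox_margin_mm)


def build_stage2_samples(manifest: Manifest, cfg: PipelineConfig,
                         jitter_seed: Optional[int] = None):
    """Per-fibula refinement samples: GT-box crops, right sides mirrored.

    With ``jitter_seed`` the crop boxes get seeded per-face padding jitter
    (see :func:`_jittered_bbox`); without it the fixed config margin is used.
    """
    rng = np.random.default_rng(jitter_seed) if jitter_seed is not None else None
    samples = []
    for rec in filter_eligible(manifest, "step2").records:
        image, masks = _load_case(rec)
        side = rec.available_sides[0]
        mask = masks[side]
        norm = normalize_hu(image)
        if rng is None:
            bbox = mask_bbox(mask, cfg.bbox_margin_mm)
        else:
            bbox = _jittered_bbox(mask, cfg, rng)
        img_c, msk_c = crop(norm, bbox), crop(mask, bbox)
        if side == "right":
            img_c, msk_c = mirror_lr(img_c), mirror_lr(msk_c)
        x = resample(img_c, cfg.stage2_shape).data.astype(np.float32)
        y = _resample_target(msk_c, cfg.stage2_shape)
        samples.append((x, y))
    return samples


def build_stage1_samples(manifest: Manifest, cfg: PipelineConfig):
    """Localization samples: whole down-sampled CTs (bilateral, joint target)
    or mirrored mid-plane halves (unilateral, single-fibula target)."""
    samples = []
    if cfg.approach == "bilateral":
        for rec in filter_eligible(manifest, "bilateral_step1").records:
            image, masks = _load_case(rec)
            norm = normalize_hu(image)
            joint = Mask(
                (masks["left"].data | masks["right"].data), image.spacing, image.origin
            )
            x = resample(norm, cfg.stage1_shape).data.astype(np.float32)
            y = _resample_target(joint, cfg.stage1_shape)
            samples.append((x, y))
    else:
        for rec in filter_eligible(manifest, "unilateral_step1").records:
            image, masks = _load_case(rec)
            side = rec.available_sides[0]
            norm = normalize_hu(image)
            img_l, img_r = split_halves(norm)
            msk_l, msk_r = split_halves(masks[side])
            if side == "left":
                img_h, msk_h = img_l, msk_l
            else:
                img_h, msk_h = mirror_lr(img_r), mirror_lr(msk_r)
            x = resample(img_h, cfg.stage1_shape).data.astype(np.float32)
            y = _resample_target(msk_h, cfg.stage1_shape)
            samples.append((x, y))
    return samples


def _split_samples(samples, seed):
    n = len(samples)
    if n < 2:
        raise ValueError("need at least two samples to hold out validation")
    n_val = max(1, n // 10)
    order = np.random.default_rng(seed).permutation(n)
    val = [samples[i] for i in order[:n_val]]
    tr = [samples[i] for i in order[n_val:]]
    return tr, val


def train_approach(manifest: Manifest, approach: str, cfg: PipelineConfig,
                   tcfg: TrainConfig, spec: NetworkSpec = NetworkSpec(),
                   stage2_weights: Optional[WeightState] = None,
                   etl_fallback_loss: float = 0.5):
    """Two-stage training: refinement from scratch, then localization
    initialized from it (Expansion Transfer Learning).

    The refinement stage sees every annotated fibula individually; passing
    ``stage2_weights`` reuses an already-trained refinement network, which is
    shared between the two approaches by construction.

    Dice-trained networks are saturated (unbounded-confidence logits), and
    fine-tuning such a prior on the coarse whole-field task can fall into the
    empty-prediction attractor of the Dice loss.  The warm-started run is
    therefore guarded: if its best validation loss stays above
    ``etl_fallback_loss``, stage 1 is retrained from random initialization
    and the run with the lower validation loss is kept.  The returned
    weights' provenance records which initialization won; ``histories``
    contains every run.  Returns ``(weights1, weights2, histories)``.
    """
    if approach != cfg.approach:
        cfg = replace(cfg, approach=approach)
    histories = {}
    if stage2_weights is None:
        s2 = build_stage2_samples(manifest, cfg, jitter_seed=tcfg.seed + 17)
        tr, va = _split_samples(s2, tcfg.seed)
        stage2_weights, histories["stage2"] = unet3d.train(
            tr, va, tcfg, spec=spec, stage="stage2"
        )
    s1 = build_stage1_samples(manifest, cfg)
    tr, va = _split_samples(s1, tcfg.seed + 1)
    init = expansion_transfer(stage2_weights)
    weights1, histories["stage1_etl"] = unet3d.train(
        tr, va, tcfg, init_weights=init, stage=f"stage1_{approach}"
    )
    best_etl = min(histories["stage1_etl"]["val_loss"])
    if best_etl > etl_fallback_loss:
        w1_scratch, histories["stage1_scratch"] = unet3d.train(
            tr, va, tcfg, spec=stage2_weights.spec, stage=f"stage1_{approach}"
        )
        if min(histories["stage1_scratch"]["val_loss"]) < best_etl:
            weights1 = w1_scratch
            weights1.provenance["init"] = "scratch_fallback"
    return weights1, stage2_weights, histories


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_TABLE_COLS = ["case_id", "side", "approach", "DS", "ASD_mm", "HD95_mm",
               "ROI_DS", "ROI_ASD_mm", "ROI_HD95_mm", "status"]


def run_experiment(manifest: Manifest, weights1: WeightState, weights2: WeightState,
                   cfg: PipelineConfig, split: str = "test") -> pd.DataFrame:
    """Per-fibula metric rows for one approach plus mean/sd aggregate rows."""
    cases = manifest.subset(split) if split else manifest
    if not len(cases):
        raise ValueError(f"no cases in split {split!r}")
    rows = []
    for rec in cases.records:
        image, gts = _load_case(rec)
        result = segment(image, weights1, weights2, cfg)
        for side, gt in gts.items():
            pred = result.masks.get(side)
            if pred is None:
                pred = Mask(np.zeros(image.shape, np.uint8), image.spacing, image.origin)
            report = evaluate_pair(gt, pred, crop_mm=cfg.crop_mm)
            rows.append({
                "case_id": rec.case_id, "side": side, "approach": cfg.approach,
                **report.as_row(), "status": result.status.get(side, "missing"),
            })
    df = pd.DataFrame(rows, columns=_TABLE_COLS)
    num = df[[c for c in _TABLE_COLS if c not in ("case_id", "side", "approach", "status")]]
    num = num.astype(float)
    agg = []
    for stat, vals in (("mean", num.mean()), ("sd", num.std())):
        agg.append({"case_id": stat, "side": "", "approach": cfg.approach,
                    **vals.to_dict(), "status": ""})
    return pd.concat([df, pd.DataFrame(agg, columns=_TABLE_COLS)], ignore_index=True)
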