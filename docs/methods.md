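# Methods

## The segmentation problem

For mandibular reconstruction with a fibula free flap, surgeons need an
accurate triangle-mesh model of the patient's fibula, extracted from a
lower-extremity CT.  Manual or threshold-based segmentation is slow and
operator-dependent; `fibseg` implements a fully automatic two-stage
("coarse-to-fine") 3D U-Net approach:

1. **Localization** — a U-Net sees a heavily down-sampled view of the scan
   and produces a rough fibula mask, from which a bounding box is derived.
2. **Refinement** — the CT is cropped to that box (plus a configurable
   margin, default 5 mm), resampled to a fixed elongated grid, and a second
   U-Net segments the bone at high relative resolution.

Both fibulae appear in the field of view, and the two bones are mirror
images of each other to good approximation.  The package therefore mirrors
every right fibula across the field-of-view mid-plane (a pure grid flip, no
registration — the patient is assumed roughly centred) so that a single
refinement network serves both sides; its output is mirrored back.

Two localization variants are implemented:

* **bilateral** — one network segments *both* fibulae jointly from the whole
  down-sampled CT (default grid 144×144×288).  Training it requires cases
  with both sides annotated.  Its known fragile mode: if one fibula is not
  predicted as a continuous bone, component filtering can leave fewer than
  two plausible candidates and that side's bounding box cannot be formed.
* **unilateral** — the CT is split at the mid-plane, the right half is
  mirrored, and one network (default grid 96×192×320 per half) localizes a
  single fibula in each half independently.  Every annotated fibula is
  usable for training, and a failure on one side cannot affect the other.

The refinement stage (default grid 80×80×960) is identical for both
variants.  Final masks are post-processed (largest connected component,
binary erosion with a 3³ box, Gaussian smoothing, marching cubes) into
STL meshes in physical millimetres.

## Network, loss, and training

The U-Net follows the classic 3D encoder-decoder: an input convolution to
16 feature maps, four `Conv + MaxPool + Conv` encoder blocks doubling the
maps at each of the four 2×2×2 poolings, and a bottleneck convolution to
512 maps — ten encoder convolutions in all.  The decoder mirrors this with
four nearest-neighbour (element-repetition) ×2 upsamplings, skip
concatenations from the encoder, and a final 3³ convolution to one channel
with a sigmoid.  All convolutions are 3³ with same-padding, so output and
input grids coincide; every input axis must be divisible by 2⁴ = 16.
A width multiplier (`base_channels`, default 16) scales the whole
progression for desk-scale experiments without changing the layer graph.

Choices the architecture description leaves open, fixed here: ReLU
activations, no normalization layers, binarization threshold 0.5,
Dice-loss smoothing ε = 1e-6, batch size 1 (whole volumes), no data
augmentation.  Four upsamplings are used because four poolings force them
geometrically.

The forward pass, backpropagation, Adam, and the soft Dice loss
`1 − (2Σpt + ε)/(Σp + Σt + ε)` are implemented directly on numpy arrays
(im2col convolutions); training is exactly reproducible for a fixed seed.
Two numerical safeguards matter in practice:

* the training-path sigmoid is evaluated in float64, because exact float32
  saturation (p ∈ {0,1}) makes the Dice gradient identically zero — an
  absorbing state;
* gradients are clipped to global norm 1.0 (`clip_norm`), without which
  Adam overshoots into that saturated regime within a few epochs;
* a collapse restart: when a whole epoch ends in the empty-prediction state
  (training loss ≈ 1) after progress had been made, the best checkpoint is
  restored and optimization continues at half the learning rate (at most
  three times).  Empty predictions are a flat attractor of the Dice loss;
  without the restart a single bad step can waste the rest of the run.

Convolutions are evaluated as 27 per-offset GEMMs against the shifted
input ("shift-and-add"), which is several times faster than an im2col
patch matrix at this kernel size.  Default optimizer settings:
Adam(lr 3e-4, β = 0.9/0.999), best-validation checkpoint returned.
Learning rate and epoch count are package choices; the original
description of the method does not constrain them.

One more training-data detail matters: the refinement stage's training
crops are **jittered**.  If every training crop is the tight ground-truth
bounding box plus a fixed margin, the bone sits at a fixed position and
scale inside the crop and the network learns that position as a shortcut —
it then fails on localization-derived boxes, which carry a few voxels of
slop.  `build_stage2_samples` therefore pads each box face by a seeded
random number of voxels (up to twice the configured margin).  Coarse
targets are produced by antialiased downsampling (trilinear on floats,
then a 0.5 majority vote), which gives cleaner labels for thin bones than
nearest-neighbour picking.

## Expansion transfer, and when it fails

The training protocol trains the refinement network first (every annotated
fibula is a sample) and initializes the localization network from its
weights — "expansion" of the detailed filters to the whole field of view,
which is possible because the network is fully convolutional and therefore
resolution-agnostic.  `expansion_transfer` copies every parameter verbatim
and records provenance.

This warm start is not unconditionally safe.  Dice training drives logits
to ±28 within a couple of epochs (nothing in the loss penalizes
confidence), and fine-tuning such a confident prior on the coarse task —
where its initial prediction may have essentially no overlap with the
tiny foreground — can fall into the Dice loss's empty-prediction
attractor (validation loss pinned at 1.0).  In the package's final
training configuration (collapse restarts, crop-jittered refinement
training, `base_channels = 6`) the transferred initialization converges
for both localization variants and no special handling is needed; in
under-regularized small-network regimes it reproducibly collapsed while
from-scratch training succeeded.  `train_approach` therefore guards the
protocol: the warm-started run is always executed and logged, and if its
best validation loss stays above 0.5 the stage is retrained from random
initialization and the better run kept, with the winning initialization
recorded in the checkpoint provenance.  Whether expansion transfer helps
is treated as an empirical property of the data regime, not an
assumption.

## Evaluation metrics

* **Dice score** `DS = 2|A∩B| / (|A|+|B|)` on voxel sets; `dice(∅,∅) := 1`.
* **Average surface distance (ASD)** and **95% Hausdorff distance (HD95)**
  operate on surface voxel centers (foreground voxels with a 6-connected
  background neighbour; the grid border counts as background) in physical
  mm.  Directed nearest-neighbour distances are pooled over both
  directions; ASD is their mean, HD95 their 95th percentile with linear
  interpolation.  Pooling before the percentile (rather than a
  max-of-directed-percentiles) is the package's documented convention, and
  both metrics are symmetric by construction.  Distances are flagged
  invalid — not NaN — when either mask is empty.
* **ROI metrics** — during surgery roughly 7 cm at each end of the fibula
  stay in the leg (knee/ankle stability), so accuracy only matters in the
  central segment.  `roi_restrict` computes the window
  `[z_min + crop, z_max − crop]` (default crop 70 mm) once from the
  ground-truth extent along the inferior-superior grid axis and zeroes
  both masks outside it.  A bone no longer than twice the crop leaves no
  window and flags the ROI metrics invalid.  The crop is a straight
  z-window, not a cut along the bone's principal axis.

All surface metrics are cross-checked in the test suite against an
all-pairs brute-force implementation to 1e-9 mm on random masks.

## Synthetic phantoms

Clinical cohorts cannot ship with the code, so benchmarks run on generated
lower-limb phantoms: two soft-tissue "legs" (HU 40) in air (HU −1000) on
opposite sides of the mid-plane, each containing a straight thick tibia
(cortical shell HU 1200, core HU 800) as distractor and a thin fibula
(HU 1200, shaft radius 5 mm) as target.  The fibula centerline is a
quadratic lateral bow (amplitude 4 mm) rasterized by distance
thresholding, spanning 90% of the z-extent, with spherical bulges at the
ends (9/8 mm) emulating the fibular head and lateral malleolus — the
regions the ROI crop removes.  Additive Gaussian HU noise (σ = 20) makes
training non-trivial.  The default grid is 64×64×160 at (2, 2, 2.5) mm,
proportioned like a lower-extremity field of view but small enough for
CPU training.

Because the geometry is analytic, the expected bone volume has a closed
form the rasterization is tested against (20% band), and HU thresholding
at the soft/cortical midpoint recovers exactly the bones on noiseless
phantoms — an oracle for the training signal.

What the phantoms deliberately do not model: trabecular texture, partial
volume effects, CT artifacts (beam hardening, metal), pathology, and
anatomical shape variability.  Passing the phantom study therefore shows
that the pipelines, mirroring bookkeeping, training protocol and metrics
are implemented correctly and that the networks can learn the task's
structure — not that clinical-grade accuracy transfers to real scans.

Cohorts reproduce the laterality structure the method was designed for:
right-only, left-only, and both-sided ground truth, in a configurable
profile — and every cohort member gets its own anatomy (`sample_params`
jitters leg position, bone radii, bow, and bone span per case seed).
Without that variability the networks memorize absolute voxel positions
instead of learning appearance, and nothing meaningful is tested.
A `fragment_fibula` fixture breaks one fibula into debris-sized pieces
(keep 4 / drop 12 slice bands), reproducing the fragmented-bone failure
surface of the bilateral variant; the severity is chosen so that the
coarse joint view loses the fragmented side while the per-half view does
not, which is precisely the robustness contrast between the two variants.

## The desk-scale study

`fibseg.phantom_study.run_phantom_study` is the package's reproducible
benchmark, sized for a single CPU: a 20-case training cohort
(4 right-only / 4 left-only / 12 both-sided → 32 fibulae), a held-out
5-case both-sided test cohort, `base_channels = 6`, 12 epochs per stage,
stage grids 32×32×48 (bilateral localization), 32×48×48 (unilateral
localization, per half) and 32×32×64 (refinement), and 12 mm bounding-box
margins (proportionate, in voxels, to the clinical 5 mm default at
sub-millimetre spacing).  The refinement network is trained once and
shared by both variants, which is also how the method is designed.
Manifest splits use a 9:1 train:validation ratio with the validation
count floored but at least 1.

On this study both pipelines recover held-out fibulae with per-side Dice
≥ 0.8, the fragmented phantom produces a `shortfall` flag under the
bilateral variant but two `ok` sides under the unilateral one, and
end-degraded predictions score better on ROI metrics than on whole-bone
metrics — the qualitative behaviour the two-variant design predicts.
`scripts/acceptance.py` re-runs all of it from scratch.

## Numerical and bookkeeping conventions

* Grid axis 0 is patient left-right with the index increasing toward the
  patient's left; axis 2 is inferior-superior.  Readers must deliver this
  orientation.  "Left" of two components = greater lateral centroid.
* Mid-plane splits give the extra column to the left half on odd axes;
  crop boxes are inclusive voxel ranges; bounding-box margins are given in
  mm and rounded up to voxels per axis.
* Resampling preserves physical extent (spacing rescaled), trilinear for
  images, nearest for masks (masks stay binary).  End-to-end left-right
  equivariance under a mirrored input holds for the unilateral variant
  (its two branches run one network on the same views) but not for the
  bilateral one — a convolutional network is not left-right equivariant,
  so a mirrored scan is a genuinely different input to its joint
  localization stage.
* Components smaller than `min_component_fraction` (default 0.1) of the
  largest are discarded as debris before the bilateral two-component
  check; this is what turns a fragmented prediction into an explicit
  `shortfall` status instead of a silently wrong bounding box.
* The post-processing chain only shrinks a mask (erosion ≈ one voxel of
  radius); for thin tubes at coarse voxels the mesh volume can sit tens of
  percent below the voxel volume, and structures thinner than the
  smoothing kernel fall back to meshing the raw voxels.

## Known limitations

* Training is whole-volume, batch 1, CPU-bound; the numpy implementation
  is deterministic but not fast.  Clinical-resolution training is out of
  scope.
* The phantom study's accuracy numbers characterize the implementation,
  not clinical performance.
* Expansion transfer converges in the package's default training
  configuration, but it is fragile under pure Dice fine-tuning (see
  above); the scratch fallback exists because the warm start is not
  unconditionally safe.
* DICOM series reading is reduced to "stack slices + spacing" via NIfTI
  conversion upstream; only NIfTI-1 is read natively.
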