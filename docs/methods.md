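# Methods

This note documents the models, algorithms and numerical choices behind
`gpseg`, in the order data flows through the package: phantom generation,
volume preparation, the network, the training objective, post-processing,
and evaluation.  It closes with the desk-scale experiment design and known
limitations.

## Scope and data model

The package segments the external and internal segments of the globus
pallidus (GPe, label 1; GPi, label 2) from a single isotropically resampled
T2-weighted volume, one subject at a time.  Volumes are NIfTI-1 files; on
load they are reoriented to the canonical right/anterior/superior axis
order, so axis 0 is always the left-right axis and the mid-sagittal plane is
the axis-0 midplane.  Voxel indices are 0-based and the centre of voxel `i`
sits at `(i + 0.5) * spacing` mm.

## Synthetic phantoms

No study data are distributed, so the package carries a generator of
bilateral GPe/GPi phantoms that emulate the geometry and contrast of a 7 T
T2 axial slab:

* **Anatomy.** Each side is a nested pair of superellipsoids
  (`|x/a|^e + |y/b|^e + |z/c|^e <= 1`, exponent drawn from U[2.0, 2.8], axis
  ratios from U[0.5, 1.2] with the shortest axis left-right, random rotation
  up to 15 degrees).  The inner body is the GPi; its semi-axes are scaled so
  the analytic volume equals a draw from a truncated normal (mean 0.63,
  SD 0.12 cm^3, clipped at 3 SDs).  The GPe is the shell between a
  concentric, shape-matched outer superellipsoid and the GPi dilated by the
  lamina thickness (default 1 mm); the outer scale is solved by rank search
  so the voxelized shell volume matches its own truncated-normal draw
  (mean 1.25, SD 0.19 cm^3).  The gap between the two structures is
  therefore exactly the lamina everywhere, and the GPi always lies inside
  the convex hull of the GPe.  Sides are mirrored about the mid-sagittal
  plane with a small independent jitter (default <= 0.5 mm per axis).
* **Contrast.** Piecewise-constant intensities follow 7 T T2 contrast of the
  iron-rich pallidum: background 120, GPe 55, GPi 75, lamina 110, vessels 25
  (arbitrary units), plus white Gaussian noise with SD 8.  Gaussian rather
  than Rician noise: at this SNR the difference is negligible for
  segmentation.
* **Corruptions.** Motion blur is a 1D Gaussian of given FWHM along a chosen
  axis with a renormalized kernel (constant images stay constant; the
  intensity sum is preserved to well under 0.1 %).  Vessels are tubes of
  given radius swept along random cubic Bezier curves through the inferior
  half of the grid; they recolour only background-labelled voxels, so label
  maps are never altered.
* **Determinism and fitting.** Everything derives from one integer seed.  An
  extreme draw that cannot fit the grid raises a geometry error;
  `sample_phantom_retry`/`generate_dataset` rederive the seed
  deterministically and redraw, which slightly truncates the upper volume
  tail on small grids (quantified in the tests by running distribution
  checks on a grid with a 37 mm field of view, where no retries occur).

The phantoms emulate *geometry, nesting topology, contrast and noise*; they
do not emulate neighbouring nuclei, bias fields, partial-volume averaging or
k-space artefacts.  Passing tests therefore demonstrate that the pipeline
can learn and measure nested low/high-intensity structures under noise — not
clinical-grade performance on real scans.

## Volume preparation

* Resampling to an isotropic grid uses nearest-neighbour interpolation for
  both intensities and labels.  Output axis length is
  `round(extent / target)` with ties up; each output voxel copies the input
  voxel whose centre is nearest in physical coordinates, ties toward the
  lower index.
* Intensities are z-scored per volume (zero mean, unit SD) before the
  network sees them; the acquisition protocol this emulates does not pin an
  intensity scale, and per-volume standardisation is the minimal
  scanner-robust choice.
* Grids are zero-extended to multiples of 2^m (m = 4 pooling stages, so 16)
  with the image minimum (images) or background (labels); a crop record
  inverts the padding exactly after inference.

## Network

A 4-stage 3D U-net with attention-gated skips and deformable convolutions in
the deep stages.  The layer table is fixed by default:

| stage      | level | type       | kernel | padding | dilation |
|------------|-------|------------|--------|---------|----------|
| encoder    | 1     | regular    | 11     | 15      | 3        |
| encoder    | 2     | regular    | 9      | 8       | 2        |
| encoder    | 3     | deformable | 5      | 2       | –        |
| encoder    | 4     | deformable | 3      | 1       | –        |
| central    | 5     | deformable | 3      | 1       | –        |
| decoder    | 4     | deformable | 3      | 1       | –        |
| decoder    | 3     | deformable | 3      | 1       | –        |
| decoder    | 2     | regular    | 5      | 2       | 1        |
| decoder    | 1     | regular    | 7      | 3      | 1        |
| final      | –     | regular    | 1      | 0       | 1        |

Every convolution is size-preserving; the only resolution changes are four
2x2x2 max-poolings and four factor-2 trilinear upsamplings.  Regular encoder
stages are two identical convolution/batch-norm/ReLU blocks; a deformable
block is an offset-predicting standard convolution (3k^3 output channels),
the deformable convolution proper (per-tap trilinear sampling at the
regular grid position plus its predicted offset; out-of-bounds reads zero),
and another standard convolution of the same kernel and padding, each
feature-producing convolution followed by batch norm and ReLU.  Offset
predictors are zero-initialized, so training starts in the
regular-convolution regime.

Attention gates sit on decoder levels 2-4.  Their internals are additive
attention: kernel-1 projections of the skip (at gating resolution, via 2x
average pooling) and of the gating signal to an intermediate width (half the
skip channels), sum, ReLU, kernel-1 projection to one channel, sigmoid, and
trilinear upsampling of the coefficients to the skip resolution.  The
central stage's output gates the deepest skip; above that, each level is
gated by the merged decoder output one level below.  Per level, the gated
skip and the upsampled decoder features are concatenated and fused by a
kernel-1 convolution; a final kernel-1 convolution yields the three class
scores, softmaxed into probabilities (argmax ties break toward the lower
class index).

**Free parameters the layer table does not fix.**  Channel widths default to
16 at level 1, doubling per level (central 256); the desk-scale experiments
use `base_channels=8`.  Upsampling is trilinear interpolation.  Decoder
convolutions carry batch norm and ReLU, mirroring the encoder; the kernel-1
fusion convolutions and the final classifier are plain convolutions.

**Initialization gain.**  Weights are He-normal scaled by a configurable
`init_gain` (default 0.05).  Because batch normalization follows every
feature convolution, the network function is invariant to the scale of those
weights, and the effective learning rate of a BN-normalized layer scales as
`lr / ||W||^2`.  At the fixed reference learning rate of 1e-4, He-magnitude
weights (`init_gain=1`) train orders of magnitude more slowly than the
published multi-day schedule can hide; a small gain makes schedules of tens
of epochs productive without touching the published optimizer settings.
Gains below ~0.02 destabilize early epochs (transiently collapsed classes);
0.05 is a stable default at desk scale.

## Numerical backend

The network and its gradients run on a small reverse-mode autodiff core
written on numpy (`gpseg.autograd`).  Convolutions pick between two exact
algorithms: an im2col GEMM for small workloads and an FFT path (real FFTs at
`next_fast_len` sizes, kernel spectra reused between forward and backward
via a conjugation/phase identity) when the patch matrix would exceed ~64 MB.
Both paths agree to round-off and are verified against numeric gradients in
the test suite.  Batched FFTs are chunked (8 transforms per call) to avoid a
memory cliff in single-call large batches.  Training runs in float32;
verification tests use float64.

## Training objective

Per step, with softmax probabilities `p` and one-hot truth `t`:

* **Tversky term.**  `TI_c = tp_c / (tp_c + alpha_c fp_c + beta_c fn_c)`
  with soft counts, weights background (0.7, 0.3), GPe (0.4, 0.6), GPi
  (0.4, 0.6) — false negatives on the small foreground structures cost
  double.  The loss is the unweighted mean over the three classes of
  `1 - TI_c` (a summed variant is config-exposed).  Two empty masks give
  index 1: a correctly absent class is not penalized.
* **Overlap penalty.**  The sum over ordered class pairs (c != c') of the
  soft Dice between predicted class c and true class c', weighted 0.01.  It
  discourages prediction mass on another class's territory (pairs involving
  background can be excluded by flag; included by default).
* **Hausdorff surrogate.**  On the whole-pallidum foreground (GPe + GPi,
  both sides together): mean of `(p_fg - t_fg)^2 (dt(t)^2 + dt(bin(p))^2)`,
  where `dt` is the Euclidean distance transform in mm of the complement of
  the mask, the prediction is binarized at 0.5, and both distance maps are
  constants within a step.  Its weight starts at 1e-5 and multiplies by 5
  every 50 epochs, so within a 94-epoch schedule it grows once.

Optimization is stochastic gradient descent, learning rate 1e-4, momentum
0.9, batch size 1, default 94 epochs; sample order reshuffles each epoch
with the run seed.  Augmentation mirrors every pair about the mid-sagittal
plane once, statically doubling the dataset before the epoch loop.  No
learning-rate decay, weight decay or early stopping; the final-epoch
checkpoint is the deliverable.

## Inference and post-processing

Inference z-scores the input, pads to a multiple of 16, runs the network in
evaluation mode (batch-norm running statistics), softmaxes, argmaxes,
inverts the padding, and removes "islands": per foreground class the
connected components (26-neighbourhood) are ranked by voxel count — ties by
the lower linear index of the first voxel — and all but the largest two per
class are cleared to background, so at most four foreground components
remain (left and right GPe and GPi).  Ranking per class rather than globally
prevents one structure's components from evicting the other class entirely.
Post-processing never adds foreground and never relabels a surviving voxel.

## Evaluation metrics

All metrics are computed per structure and per side, the sides split at the
axis-0 midplane.  Surfaces are centres of mask voxels with at least one
6-neighbour outside the mask (the grid boundary counts as outside); there is
no sub-voxel meshing.  Dice is `2|A ∩ B| / (|A| + |B|)` (1 for two empty
masks); centre-of-mass distance uses unweighted voxel-centre centroids in
mm; the mean surface distance is the symmetric average of the two directed
mean nearest-surface distances (a directed variant is available by flag);
the Hausdorff distance is the bidirectional max-min surface distance;
volumes are voxel count x voxel volume / 1000 (cm^3); precision and recall
follow the usual tp ratios with an empty denominator scoring 1.  Distance
metrics are undefined (and flagged) for empty masks.  Method comparison uses
one-way ANOVA followed by all-pairs Tukey honest-significant-difference
tests, with cells categorized at the 0.1 % and 5 % levels; Tukey's
family-wise control is the multiple-comparison correction.

## Desk-scale experiment design

The published training run (58 subjects, 0.39 mm grids, 94 epochs, days of
GPU time) is far outside a single-CPU test budget, so the package's
end-to-end experiment is deliberately small, with two constraints that
interact:

* **Field of view.**  Bilateral pallidal anatomy at the reported volumes
  spans 23-26 mm anterior-posterior, so the grid must offer >= ~30 mm; the
  experiment uses 32³ voxels at 1.0 mm (32 mm field of view).  At this
  spacing the GPe shell is only 2-3 voxels thick, which caps the achievable
  Dice well below what the acquisition-matched 0.39 mm grid allows — the
  experiment measures that the pipeline learns and localizes the anatomy,
  not the headline overlap of the full-scale system.
* **Steps.**  Six training phantoms (twelve pairs after mirroring) for 30
  epochs — 360 SGD steps — fit the budget.  Under the published optimizer
  settings the GPi converges within this schedule; the thin GPe shell
  converges much more slowly (its larger soft-count denominators shrink the
  per-voxel gradients, and the halo of background it initially captures is
  carved away at a roughly constant slow rate), and its Dice is still
  climbing when the schedule ends.

The acceptance experiment therefore reports, per structure: mean test Dice,
centre-of-mass error, mean surface distance, volumes, precision/recall and
the component count after cleanup.

## Known limitations

* The phantom is a geometric idealization; none of the acceptance numbers
  transfer to real 7 T data.
* At 1 mm desk-scale spacing the GPe shell is near the resolution limit;
  its Dice under-reports what the same pipeline reaches on finer grids.
* The numpy backend is exact but slow (seconds per training step at 48³);
  it is meant for verification and desk-scale experiments, not full-scale
  training.
* Batch-norm statistics come from batch-size-1 training; evaluation-mode
  running statistics lag early in short schedules.
* Left/right assignment is by grid midplane, not anatomy; a laterally
  shifted subject would need registration first.
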