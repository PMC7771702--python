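# Methods

## Problem and model

Stereotactic procedures in rodents place probes relative to **bregma**
(sagittal × coronal suture intersection, anterior) and **lambda**
(sagittal × lambdoid intersection, posterior).  skullmark localises both
points in an overhead photograph with a two-stage pipeline:

1. **ROI stage.** The photograph is downsampled by an integer factor
   (default 4; 2448 × 3264 → 612 × 816) with area averaging.  A detector
   proposes the skull bounding box in this frame; the box is scaled back
   by the same factor and a fixed-size square crop (default 640) is
   centred on it, translated the minimum distance needed to stay inside
   the image.  The crop is downsampled by the exact crop/net ratio
   (640/256 = 2.5) to the network input.  All of this geometry is
   recorded in a `CropWindow`, and coordinates move between frames by
   exact affine maps — labels are never resampled, only regenerated.
2. **Heatmap regression.** Each landmark is supervised as a truncated,
   un-normalised 2-D Gaussian (peak 1.0, σ = 20 px on the 256 grid,
   truncated to exact zero beyond 3σ).  The network regresses the
   two-channel heatmap under pixel-wise MSE with Adam (lr 0.001,
   batch 8); the prediction is the per-channel argmax, scaled by 2.5
   into the crop frame.  Argmax decoding recovers any in-grid centre
   exactly, so the codec contributes no error beyond integer-pixel
   quantisation (≤ ~0.7 px in the net frame).

### Architecture

Conv-1: three 3×3 convolutions, stride 2 on the first (the earliest
reduction is the cheapest place to halve the resolution), channels
3 → 32.  Bottleneck blocks 1–3: 3/4/6 residual bottleneck layers with
output channels 128/256/512; the first layer of each block has stride 2
and a projected (1×1, strided) shortcut, the rest are identity
shortcuts.  A bottleneck layer is 1×1 (compress to n_out/4) → 3×3
(stride) → 1×1 (expand), each conv followed by batch norm, with ReLU
after the first two and after the residual addition.  Three
deconvolution branches return the block outputs to the input resolution:
2/3/4 steps of stride-2 3×3 transposed convolutions (halving channels
per step, each with BN + ReLU) and a final 1×1 convolution to 2
channels.  The three n×n×2 outputs are concatenated (n×n×6) and fused by
a 3×3 convolution to 16 channels (BN + ReLU) and a final linear 3×3
convolution to 2 channels — no activation, so the output can match the
Gaussian label directly.

Width scales with a single multiplier (¼ for the tiny preset), keeping
the 1:4:8:16 channel ratios; the net size must be divisible by 16 (four
×2 reductions).

### Decoding order

The reference procedure upsamples the predicted heatmap to the crop size
before taking the argmax; this implementation takes the argmax at net
resolution and multiplies the coordinate by the scale (2.5), which is
equivalent up to interpolation smoothing and cheaper.  A flag
(`predict_landmarks(..., upscale_first=True)`) reproduces the
upsample-first order.

## Numpy engine

No deep-learning framework is used: `skullmark.nn` is a small,
deterministic CPU engine written for exactly the layers this
architecture needs.  Convolutions are evaluated as k² shifted
channel-matmuls (BLAS `tensordot`), transposed convolutions as their
exact adjoint; batch norm, ReLU, linear, flatten, Adam and MSE complete
the set.  Every backward pass is hand-derived and checked against
numerical differentiation in the test suite.  All state is float32 and
every random draw flows through an injected `numpy.random.Generator`, so
training runs are bit-reproducible from a seed.  He initialisation for
convolutions; batch-norm parameters start at unit gamma / zero beta,
**except the last batch norm of every residual bottleneck, whose gamma
starts at zero** (the standard residual zero-gamma trick): each block is
then the identity at initialisation, which markedly speeds convergence
at the small step budgets the CPU protocols use.  Without it the tiny
protocol cannot fit even its own training crops in the allotted epochs.
The final (linear) output convolution starts with its weights scaled to
near zero (`head_init_scale`, default 0.01), so the initial prediction
roughly matches the mostly-zero Gaussian labels; this removes most
seed-to-seed variance of the training outcome.

## Synthetic scenes

The generator emulates the statistical structure of skull photographs so
that every stage is trainable and testable without data:

* a bright, **egg-shaped** skull plate (ellipse with the lateral
  semi-axis modulated by `1 − 0.25·t` along the anterior axis — real
  crania narrow toward the snout, and this low-frequency asymmetry is
  what tells bregma from lambda at any orientation) on a darker,
  coarsely textured background;
* a sagittal midline suture through both landmarks; a shallow-angled
  coronal suture pair crossing at bregma (sweep 15° from transverse) and
  a steep chevron-shaped lambdoid pair with its apex at lambda (48°),
  mirroring the differing shapes of the real sutures;
* 1–3 dark vessel-like curves parallel to the midline (the main
  real-world confuser near the sagittal suture);
* a linear lighting ramp of random direction and strength (5–25%) and
  additive Gaussian pixel noise (sd 6 of 255), uncontrolled orientation
  uniform in [0°, 360°).

Landmarks and bounding boxes are computed **analytically from the curve
parameters** (and re-derivable by intersecting the suture lines), never
read back from pixels, so ground truth is exact.  Suture width is fixed
at 3 px *in crop pixels* for every preset: the crop/net ratio is 2.5
everywhere, so sutures subtend the same ~1.2 net pixels at either scale
and the tiny preset remains a faithful scaled replica rather than a
harder task.  Scene parameters draw from a per-scene seed derived from
the master seed by a counter scheme, making datasets extensible without
reshuffling.

The full preset matches the photographic geometry (2448 × 3264 canvas,
factor-4 lowres, 640-crop, 256-net, bregma–lambda distance uniform in
[140, 190] px around the measured ≈163 px); the tiny preset is its
4×-reduced replica (612 × 816, 160-crop, 64-net, distances in
[35, 47.5] px).  What the generator does **not** emulate: fur and skin
around the exposed skull, specular reflections, perspective, bone
texture, and anatomical variability of suture shapes.  Passing tests on
these scenes therefore demonstrate that the pipeline's geometry, labels,
training loop and decoding are correct and that the architecture can
learn this landmark task at a scaled protocol — not that the shipped
weights transfer to real photographs.

### σ convention at reduced resolution

The label width is specified in the reference 256-net frame (σ = 20 px
there) and scaled by `net_size/256` for other working resolutions, so
the bump's extent relative to the skull is resolution-invariant; the
tiny 64-net preset therefore trains with an in-grid σ of 5.  The σ sweep
takes its values (5, 10, 20, 40) in the reference frame and scales them
the same way.

## Detectors

The ROI stage accepts any object with `detect(lowres_image) →
RoiDetection`; one skull per image is assumed (resolved by max score).

* **Otsu baseline** — Gaussian smoothing, Otsu threshold, largest
  connected component.  Deterministic and training-free; refuses images
  whose foreground/background contrast is below a floor (pure noise) or
  whose largest component has implausible area.
* **Convolutional box regressor** — four stride-2 3×3 convolutions and a
  flatten + linear head predicting (centre, log-size), trained with MSE
  on whitened targets.  Design notes: per-image standardisation (robust
  to the lighting ramp); no batch norm (it measurably slows coordinate
  regression through a flatten head at this batch size); box-consistent
  shift/flip jitter at every step, without which the network memorises
  the few training scenes instead of learning translation covariance;
  learning-rate drop (×0.15) for the last quarter of training; flip
  test-time averaging.  The regressor is resolution-locked: feeding an
  image of a different size than it was trained at is an error.

## Augmentation and cross-validation

Augmentation shifts the crop window inside the full image (±10% of the
crop size per axis), rotates the cropped content about the crop centre
(uniform [0°, 360°)) and flips horizontally/vertically (p = 0.5 each).
Landmarks are pushed through the same analytic similarity transform and
labels regenerated in the new frame; a draw that expels a landmark from
the crop is retried (cap 25).  The default plan makes 100 copies per
training image.  The cross-validation layout splits n images into five
subsets — a fixed test subset (13/93 of the data) and four rotating
subsets; each fold trains on three subsets (augmented), validates on the
fourth (originals only) and never touches the test subset.

## Evaluation

Errors are Euclidean distances in the crop frame, where the anatomical
calibration holds: 4.2 mm ≈ 163.20 px ⇒ 25.74 µm/px.  By default the
conversion is computed from the test set's own mean ground-truth
bregma–lambda pixel distance (mirroring how the published calibration
was obtained), with a fixed override available.  Each error vector is
also decomposed along the ground-truth tail-head axis (normalised
bregma − lambda) and its left-right perpendicular; the squared
components sum to the squared error by construction.  Scenes where the
detector refuses are excluded from the means and counted in a failure
tally rather than given a penalty distance.

## Tiny protocol (the CPU-scale experiment)

50 synthetic scenes × 4 augmented crops = 200 training pairs, 8
validation scenes (un-augmented ground-truth-window crops), 64-net /
quarter-width network, 30 epochs of Adam (lr 0.001, batch 8), best
validation checkpoint kept, then the full two-stage pipeline (Otsu
detector) evaluated on 20 held-out scenes.  Sizes were chosen so a run
takes ~2–3 minutes on one CPU core while preserving the structure of the
full protocol (augmented training / original validation / untouched
test, same crop/net ratio, same σ convention).  Train, validation and
test scene seeds live in disjoint namespaces of the master seed.

## Numerical choices and degenerate inputs

* Argmax ties break to the smallest row-major index; a constant heatmap
  decodes to (0, 0) deterministically.
* Gaussian labels are evaluated at integer pixel centres with the mean
  kept at full precision (no rounding); truncation at 3σ keeps > 98.9%
  of the mass and makes sparsity exactly testable.
* Crop windows are clamped by translation (never shrunk, as the network
  needs a fixed input size); images smaller than the crop are
  edge-replicated.
* Coordinates are 0-based (row, col) with the origin at the top-left
  pixel centre in every frame.
* The point maps between frames are the exact affines `full = origin +
  net · scale`; the ≤ 0.75-px half-pixel offset of area resampling
  relative to this convention is accepted and identical in training and
  evaluation.
* MSE is accumulated in float64 so the training-loop loss equals a
  brute-force per-pixel sum to 1e−10.

## Known limitations

* The synthetic scenes are deliberately schematic; absolute error
  magnitudes on them do not predict real-photograph performance.
* The quarter-width tiny protocol is capacity- and data-limited by
  design; its errors are reported in net pixels and are the scaled
  analogue, not a reproduction, of full-scale results.
* The bundled detectors assume exactly one bright skull per image.
* Training is single-threaded deterministic numpy; it is CPU-bound and
  not intended for full-resolution (256-net, full-width) training runs.
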