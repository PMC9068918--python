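# Methods

## The imaging problem

A lensless chip-scale fluorescence sensor reports, for each pixel, the
sum of light emitted by labeled cells at every depth of the specimen,
each depth contributing through a progressively wider point spread
function (PSF). The forward model treated here is linear and
shift-invariant per depth: a specimen is an ordered stack of thin
layers, the acquisition is

    y = Σ_k  h(z_k) * x_k

where `x_k` is the fluorescence image of layer k at depth `z_k`, `h(z)`
the PSF at depth `z`, and `*` 2D convolution. Two sensors facing each
other across a 1 mm specimen see complementary degradation: sensor A
blurs layer k with `h(z_k)`, sensor B with `h(1 mm − z_k)`, which is
what makes mid-stack and far layers recoverable from a single pair of
acquisitions.

## Phantom generator

Single-layer phantoms emulate fluorescence images of tumor-cell foci on
a 51×51 grid:

- **Structure.** Classic 2D lattice-gradient (Perlin) noise:
  pseudorandom unit gradients on an integer lattice, quintic-smoothstep
  interpolated dot products, octaves summed with geometric persistence,
  min-max normalized to [0, 1]. Thresholding at 0.5 gives the binary
  tumor mask; the coherent structure of the noise makes the mask smooth
  foci rather than speckle (mean connected-component area at defaults is
  tens of pixels; frame occupancy ≈ 0.5).
- **Intensities.** Per-pixel draws from two Gaussian populations —
  signal on mask pixels, background elsewhere — clipped at zero. The
  per-image statistics are themselves drawn: SNR (signal mean over
  background mean) uniform in [2, 10], background mean uniform in
  [50, 150] arbitrary units, standard deviations a fixed coefficient of
  variation (0.15) of the respective means. These ranges are tunable
  configuration, intended to bracket realistic chip-scale fluorescence
  contrast; they are not calibrated to any particular instrument.

Defaults: grid_period 10 px, octaves 1, persistence 0.5, threshold 0.5.
A period of ~10 px on a 51×51 frame gives focus sizes of roughly 5–15 px,
matching the visual scale of multi-cellular clusters at this resolution.

What the generator does **not** emulate: tissue scattering and
absorption, laser non-uniformity, sensor read noise and quantization,
and correlation between layers (layers are independent draws). Passing
results on these phantoms demonstrate the pipeline's mechanics, not
performance on real tissue.

## PSF family

The default PSF is an isotropic Gaussian whose width grows linearly
with depth, σ(z) = σ₀ + s·z with σ₀ = 0.5 px and s = 4 px/mm, truncated
at 3σ and renormalized (flux conservation: kernels sum to 1, so depth
attenuation arises purely from spreading). At 1 mm this gives σ = 4.5 px
— heavy blur on a 51×51 frame. A flat-disc kind and a `measured` kind
(nearest-neighbor lookup in a bank of calibration kernels) share the
same interface, so chip calibration data can replace the parametric
family without touching anything downstream. Convolution is zero-padded
("dark tissue outside the frame"); reflect/wrap boundaries would be
unphysical for a dark-field fluorescence scene. All computation is in
pixel units; `pixel_pitch_um` exists only for axis labeling.

## Datasets

All builders are pure functions of (configuration, seed); child seeds
are spawned per sample with `numpy.random.SeedSequence`, and train/test
splits use disjoint streams.

- **Depth**: one layer at one of 20 bin-center depths 50, 150, …,
  1950 µm; label = bin index.
- **Deblur**: (blurred, sharp) pairs at continuous uniform depths in
  [0, 1] mm.
- **Two-layer (non-overlapping)**: two depths ≥ 500 µm apart in
  [0, 1] mm (rejection sampling); overlapping mask regions are removed
  from both layers and repainted with background before blurring, so
  each cell pixel has exactly one depth; label = per-pixel depth map,
  0 background, z/1 mm on cells.
- **Four-layer (overlapping)**: one layer per 250 µm bin with adjacent
  gaps ≥ 200 µm enforced by rejection; overlaps kept; label = the four
  binary layer masks ordered by distance from sensor A; optional dual
  acquisition.
- **Dynamics**: four-step sequences over a fixed four-layer background
  scene. A single connected Perlin focus (the "cluster") is reserved —
  its footprint is cleared from every base layer — and occupies exactly
  one layer per step, hopping from layer 0 to layer 3. Clearing the
  footprint keeps the total cell count constant across steps, so any
  change in the labels is attributable to the cluster's motion.

## Networks and training

The networks are trained with an in-package NumPy engine: im2col
convolutions (GEMM), transposed convolutions implemented as the exact
adjoint of strided convolution, ReLU/sigmoid, residual blocks, Adam
(lr 10⁻³, β = 0.9/0.999), mini-batches of 32, He initialization, all in
float32 with manual backpropagation. Training is bit-reproducible given
a seed.

- **Depth classifier**: three stride-2 3×3 conv stages (16, 32, 64
  channels) + FC head (256 → 20), softmax cross-entropy. Its input is
  the *normalized log power spectrum* of the view (Hann-windowed,
  centered, min-max scaled — still 51×51×1). Rationale: a Gaussian PSF
  attenuates power as exp(−(2πσf)²), so depth lives in the spectral
  roll-off; on raw pixels the scene's random structure masks the
  sub-pixel width differences between adjacent 100 µm bins, while in
  log-spectral coordinates the roll-off is a large, nearly linear
  feature. Windowing matters: boundary leakage otherwise floors the
  spectrum far above the signal at informative frequencies.
- **Deblurrer**: encoder-decoder with 3 stride-2 convolutions (16, 32,
  64 channels) and 3 transposed convolutions mirrored, linear output,
  MSE loss on per-view min-max normalized images; outputs clamped to
  [0, 1] at inference.
- **Detectors**: the same encoder-decoder with 1 (single-sensor) or 2
  (dual) input channels and 4 sigmoid output planes, per-pixel binary
  cross-entropy; the two-layer depth-map variant uses 1 sigmoid output
  plane and MSE. Output planes follow the sorted-layer convention
  (plane k = k-th layer by distance from sensor A), not fixed depth
  bins.
- **Residual detector**: full-resolution residual feature extractor
  (3×3 conv stem, identity-skip blocks) with a 2-convolution head
  emitting the 4 planes. No pretrained weights are used; the extractor
  is trained from scratch. Depth/width are configurable; the dynamics
  experiment uses a compact setting (8 channels, 2 blocks) sized for
  CPU training.

Per-view min-max normalization to [0, 1] at the input boundary makes
all modules invariant to the acquisition's global gain and offset.

## Metrics

- pixel error rate: fraction of pixels whose thresholded (0.5)
  prediction disagrees with the binary truth; equals 1 − accuracy.
- sensitivity TP/(TP+FN) over ground-truth cell pixels, specificity
  TN/(TN+FP) over ground-truth empty pixels; planes with no positive
  (or no negative) truth are excluded from averages with a warning.
- mean normalized deviation (continuous maps): mean |pred − truth| over
  the dynamic range of the truth.
- Multi-sample reporting is per-sample-then-average; ROC pools pixels
  across layers and samples (scikit-learn curve, trapezoidal AUC).
- 3D reconstruction: thresholded planes placed at the nearest slice of
  a 50 µm z-grid spanning the sensor separation, exported as a voxel
  CSV and TIFF stack.

## Problem sizes and observed behavior

The test suite and the acceptance script run at desk scale, sized for a
single CPU: 2,000 training / 200 test samples for depth and deblurring,
1,500/200 for the detectors, 800 training samples and 25 sequences for
the dynamics experiment, with 10–30 epochs per task. At this scale the
depth classifier resolves all 20 bins essentially perfectly (the
log-spectral representation makes the task nearly deterministic in the
noise-free forward model), the deblurrer reaches a mean normalized
pixel error below 10%, and the detector comparison reproduces the
dual-sensor effect: single-sensor error grows monotonically with depth
(~22% near, ~42% far), while the dual detector is symmetric (~19-21%
outer layers) and strictly better on the middle layers. The two-layer
depth-map regression is the task most sensitive to training-set size
and sits near 25% mean deviation at this scale.

## Known limitations

- No noise term in the forward model by default; with sensor noise the
  log-spectral depth cue would degrade gracefully but measurably.
- The truncated Gaussian PSF has near-zero spectral nulls at deeper
  depths, which makes exact linear inversion ill-posed there — one
  reason learned deblurring is preferable to Wiener filtering for
  multi-depth composites.
- Layers are statistically independent; real tissue exhibits
  correlated structure across depth.
- Error rates at desk scale are upper bounds on what larger training
  sets achieve; they shrink substantially with more samples and epochs.
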