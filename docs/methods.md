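# Methods

This document records the scientific model behind `radscan`, the assumptions
baked into each stage, the default parameter choices and why they are safe,
and the known limitations.

## 1. Problem and approach

The package classifies lung nodules in chest CT as benign or malignant from
two complementary encodings of the same nodule:

1. the windowed grayscale subvolume (a fixed 32×32×32 "nodule box"), and
2. a **shape matrix**: for every slice, the distance from the region-of-
   interest (ROI) centroid to the ROI boundary is sampled at regular angular
   increments (a *radial scan*), and the per-slice series are stacked into a
   slices × angles matrix.

The intuition is morphological: benign nodules tend to have smooth, round
cross-sections (near-constant radial series), while malignant nodules are
spiculated (radial series with large high-frequency excursions).  The shape
matrix makes that contrast explicit while the gray volume retains texture.
Both are fused into one 4D tensor and classified by a small U-shaped
encoder–decoder built from a generalized 4D convolution.

## 2. Pipeline stages and assumptions

### 2.1 HU windowing (`preprocess.window_hu`)

Hounsfield units are mapped linearly to [0, 255] using a window of width
1600 HU centered at −600 HU (the standard lung window).  Values outside the
window clamp to 0/255.  Assumption: the scanner's rescale slope/intercept
have already been applied (the DICOM reader does this).

### 2.2 Binarization and ROI extraction (`preprocess`)

Each grayscale slice is binarized with Otsu's threshold and 8-connected
components of at least `min_roi_area` pixels (default 9) are kept, ordered
by decreasing area; the largest is taken as the nodule cross-section.  The
**pole** for radial scanning is the unweighted centroid of the ROI pixels
(pixel-center convention).  Assumption: after windowing, the nodule is the
dominant bright object in its box — true for cropped nodule boxes, not for
whole slices.

### 2.3 Boundary tracing (`boundary.trace_boundary`)

Moore-neighbor tracing produces the ordered closed polygon of boundary
*pixel centers*.  This is hand-implemented: library contour extractors
(e.g. marching squares) return sub-pixel iso-contours, a different contract.
Interior holes are ignored; an ROI that is a single row or column of pixels
is degenerate (no closed curve) and raises an error, which the pipeline
converts to an all-zero shape-matrix row.

### 2.4 Closed-curve simplification (`boundary.dp_simplify_closed`)

Douglas–Peucker simplification adapted to closed curves: the curve is split
at the vertex farthest from the pole (a rotation-invariant anchor), the two
halves are simplified recursively, and the ε-Hausdorff guarantee is
preserved (every removed vertex is within ε of the simplified polyline).
When large ε would collapse the polygon below 3 vertices, the vertex
farthest from the anchor chord is retained, returning a triangle, so the
closed-polygon invariant always holds.  Default ε = 0.8 px removes pixel
staircase artifacts while keeping spiculation lobes (which are several
pixels deep at the synthetic scale).

### 2.5 Radial scan (`radial.radial_series`)

Rays leave the pole at `n_angles` regular increments (default 32, i.e.
11.25°).  Each ray's intersection with every polygon edge is found by a 2×2
linear solve; the default reports the **farthest** intersection (the
silhouette radius), with the nearest available by configuration — the two
differ only for non-star-shaped cross-sections.  A pole outside the polygon
yields an all-zero series with a warning.  Per-nodule max normalization
(default) scales the whole matrix into [0, 1] while preserving inter-slice
size relations; per-slice normalization is available when only per-slice
shape matters.

### 2.6 Joint 4D input (`unet4d.assemble_input`)

The network input is a (channel-plane, depth, height, width) tensor of
extent 2×32×32×32: plane 0 is the gray volume rescaled to [0, 1]; plane 1
broadcasts each slice's radial series across that slice's rows, so each
voxel column in plane 1 carries the boundary radius at the matching angle.
This is one concrete reading of "joint 4D input"; the embedding is exact and
invertible for plane 0.

### 2.7 Generalized 4D convolution and U-Net (`unet4d`)

Two reference implementations of the convolution (2D and 4D valid
cross-correlation with per-channel kernels and bias) are kept alongside a
fast compiled path; tests assert fast ≡ reference ≡ nested-loop oracle.
The 2D reference *subtracts* its bias by default and the 4D reference *adds*
it, mirroring the two sign conventions that coexist in the source equations;
the network itself uses "+b" uniformly and the sign is switchable per
`ConvSpec`.

The classifier is a U-shaped encoder–decoder: each encoder level applies
two 4D convolutions (the first consumes the extent-2 channel-plane axis,
later ones use 1×3×3×3 kernels with same-padding) followed by 2× max-pooling
on the three spatial axes only; the decoder mirrors with nearest-neighbor
upsampling and skip concatenation; a final 1-extent convolution maps to C
class channels and a global-average + softmax head yields one probability
vector per nodule.  Nodule-level output is used because every evaluation
metric is nodule-level.

### 2.8 Training (`unet4d.train`)

Adam with seeded He-style initialization, softmax cross-entropy, shuffled
mini-batches.  Three numerically motivated defaults:

- **Batch normalization** (`batch_norm = True`): every non-head convolution
  normalizes its linear output per channel over the batch and all positions
  before a trainable affine (gamma, beta) and the ReLU; the convolution
  bias is dropped as redundant.  Without it, training sits for dozens of
  epochs at the constant-output saddle (the model predicts the majority
  class everywhere, loss ≈ the label entropy) because the all-positive
  inputs and activations leave many filters dead and the landscape badly
  conditioned; escapes from the saddle were slow and fragile.  With BN the
  loss decreases monotonically from the first epoch and both the base-4 and
  base-8 models fit 50-sample classes within ~8 epochs.  Inference uses
  running statistics; because momentum-averaged statistics are stale after
  short trainings, `train` ends with one exact calibration pass that sets
  them to the true training-set activation statistics.
- **Gradient clipping** (`grad_clip = 5.0`, global norm): once the model
  fits the training set, per-sample margins grow without bound and a single
  outsized gradient step can destroy the learned features (observed as a
  loss spike from ≈0.1 to ≈0.9 followed by collapse to majority-class
  prediction).  Clipping removes this failure mode without altering
  well-scaled steps.
- **Learning rate 5×10⁻³**: with batch norm, 3×10⁻³ to 10⁻² all converge
  stably; 5×10⁻³ was fastest at 8 epochs in pilots and is the default.

### 2.9 Class balancing and evaluation (`balance_metrics`)

Stratified k-fold cross-validation (default 10).  Inside each training fold
the minority class is brought to parity with SMOTE — synthetic samples are
convex combinations `x + u·(x_nn − x)` of a minority sample and one of its
k nearest minority neighbors (k = 5), computed in the flattened
volume + shape-matrix feature space.  Synthetic samples never reach a test
fold; this is asserted on every run.  Metrics are the standard
contingency-table recall, precision, accuracy and F1; zero denominators
warn and report 0.

## 3. Synthetic data generator (`synthetic`)

Each nodule box contains a single connected region whose per-slice boundary
radius is `r(θ, z) = r₀ · profile(z) · (1 + a · bumps(θ, z))`: a sphere-like
base profile modulated by smooth random lobes of relative amplitude `a`
(default 0.05 for benign, 0.35 for malignant, 6 spiculation lobes), plus
grayscale texture noise (σ = 20 gray levels) and a darker background.
Realism limits: no sub-solid/ground-glass textures, no pleural attachment,
no vasculature, single nodule per box, isotropic voxels.  The generator is
a *separability phantom* for exercising the pipeline, not a clinical
simulator.

## 4. Numerical notes

- The forward/backward passes run in float32 for speed; `build_unet` takes
  a `dtype` argument so verification can run in float64.
- Finite-difference gradient checks must avoid two *structural* kinks that
  exist at standard initialization: (a) with zero-initialized biases, any
  dead receptive field (all-zero window, common with ReLU + zero padding)
  has pre-activation exactly equal to the bias, i.e. exactly 0, so the loss
  is kinked along every bias direction (the analytic gradient equals the
  left one-sided slope); (b) all-zero max-pool windows create exact 8-way
  ties whose tie-sharing subgradient differs from a two-sided difference.
  The gradient tests therefore offset biases by +0.05 before checking.
- SMOTE, fold assignment, weight init, batch shuffling and the data
  generator are all independently seeded; every artifact is reproducible
  from (config, seed).

## 5. Limitations

- The 4D convolution is implemented directly (NumPy + numba); it is fast
  enough for desk-scale experiments (tens of seconds per epoch on dozens of
  32³ samples, one CPU) but not for archive-scale training.
- Default `n_angles = 32` ties the shape matrix to the box size so the two
  input planes can share one tensor; finer angular sampling (e.g. 64 via
  5.625° increments, or 180 via 2°) is supported in `radial` but requires a
  matching tensor design to feed the network.
- The farthest-intersection convention makes the series single-valued on
  non-star-shaped sections by construction; concavity information on such
  sections is partially lost.
- Performance numbers obtained on the synthetic phantom do not transfer to
  clinical data; the generator exists to validate mechanism, not to make
  clinical claims.
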