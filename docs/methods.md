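# Methods

## Problem setting

Aerial census surveys photograph a sampling strip from a light aircraft and
count the animals in each frame. Animals appear as small elongated dark
shapes at essentially arbitrary orientation, on a textured grassland
background whose brightness varies with exposure and sun angle. A
per-pixel detector for this task must therefore respond identically to a
body pointing north and the same body pointing south-east — the descriptor
it classifies has to be rotation invariant by construction, not by
orientation augmentation.

## Rotation-invariant Fourier HOG descriptors

### Gradient encoding

The grayscale image `I` is differentiated with central differences
(one-sided at the borders), giving a complex gradient field
`G = ∂I/∂x + i ∂I/∂y = r e^{iθ}` per pixel. Treating each pixel's
orientation distribution as a Dirac delta of mass `r` at `θ` and expanding
it in a Fourier series gives the per-pixel coefficients

    F_m = r e^{imθ},  m = 0 … M_max,

stored as `M_max + 1` complex planes. We use the angular-frequency
convention (`θ` is the plain angle in radians); only the shift property of
the transform matters for the invariance algebra, so the choice of
convention is free, and this one makes a rotation by `α` act as
multiplication by `e^{imα}`. `F_0` is the (real) gradient magnitude and
`|F_m| = r` for every mode.

### Circular harmonic pooling

Spatial context is pooled by convolving each plane with circular harmonic
kernels `U_{j,k}(ρ, ψ) = w_j(ρ) e^{ikψ}`: `w_j` is a Gaussian annulus
(ring) profile and `k` the angular wavenumber. The convolution is
implemented as correlation with the conjugated kernel under reflect
padding; with that orientation a raw feature `X_{k,m} = U_{j,k} * F_m`
evaluated at the rotation centre transforms as

    X'_{k,m} = e^{iα(m−k)} X_{k,m}

under an image rotation by `α`. Invariant quantities are then

* **singles** `X_{k,m}` with `m = k` (real and imaginary part),
* **composites** `X_{k1,m1} X_{k2,m2}` with `m1 − k1 + m2 − k2 = 0`,
* optionally **magnitudes** `|X_{k,m}|` (trivially invariant, off by
  default).

Spec construction rejects any entry violating these conditions; this is a
hard error, not a warning, because a single non-invariant entry silently
destroys the property the whole descriptor exists for.

Coordinates are row-major with the origin top-left, `x` the column and `y`
the row. In this (left-handed, y-down) frame `np.rot90` is a rotation by
`α = −π/2`, which the covariance tests use explicitly. One numerical
subtlety: a circular harmonic with `k ≠ 0` vanishes at the origin, where
the angle is undefined; the kernel's centre pixel is therefore zeroed for
`k ≠ 0` (naively `atan2(0, 0) = 0` would give it full weight and break the
otherwise exact 90° grid symmetry).

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| window | 24 px | comfortably covers the default synthetic animal (10 × 4 px body) plus context |
| M_max, K_max | 4, 4 | low-order harmonics carry the body-shape signal; feature count stays tractable |
| rings | 4, centred at 0, s, 2s, 3s with s = radius/3 | concentric rings spanning the window, smooth Gaussian overlap (σ = s/2) avoids ringing |
| composite budget | 40 | all admissible pairs grow combinatorially; pairs with `|j1 − j2| ≤ 1` ordered by `(j1,k1,m1,j2,k2,m2)` are kept |

With these defaults the descriptor has 120 real entries (40 from singles,
80 from composites). Kernel-side convolutions use FFTs on a reflect-padded
image; the exactness of this shortcut is checked against a pure double-loop
implementation (equivalence to 1e−10 relative on 15 × 15 images).

## Detection pipeline

1. **Grayscale** via BT.601 luma weights (0.299, 0.587, 0.114).
2. **Local-contrast pre-filter**: a pixel enters the scan only if the
   intensity standard deviation in a `contrast_window` neighbourhood
   exceeds `contrast_threshold`. Defaults are window 9 px and threshold
   0.05: the window spans the animal's width so the body interior does not
   register as "uniform" (a 5-px window leaves a low-contrast spine along
   the body axis that splits one animal into two parallel positive
   stripes), and 0.05 sits between the measured blob-interior contrast
   (≥ 0.095) and background texture (≤ 0.04) of the default scene. Because
   the statistic scales with the global light level, dim scenes drop below
   threshold first — the mechanism behind the under-counting-in-the-dark
   behaviour the evaluation module quantifies.
3. **Per-pixel classification** with AdaBoost over depth-2 decision trees
   (100 rounds, learning rate 1.0, fixed seed). The boosting machinery is
   scikit-learn's; only the descriptors are ours. Stride is 1 by default
   (every masked pixel is classified); the score cut is 0.5.
4. **Grouping**: 8-connected components of the positive mask; each
   component is one counted animal (diagonal adjacency on a small body
   must not split it). No minimum-area filter by default; `min_area` is
   config-exposed.

### Training-sample harvesting

Positives are extracted at each annotated centroid displaced by a uniform
integer jitter of up to 2 px per axis. The jitter serves two purposes:
manual centroid clicks are not pixel-accurate, and the detector classifies
*every* masked pixel, so the positive class must cover a small contiguous
neighbourhood of the true centre or the positive response fragments and
grouping over-counts. Negatives are uniform random locations at least one
window-diameter from every annotation. An optional bootstrap round
(`bootstrap_train`) runs the current detector on further images, passes
each detection to a correction callback (a human in the field protocol, a
ground-truth oracle in tests) and appends the corrected labels — the
classic check-and-correct loop for growing a training set cheaply.

## Synthetic scenes

The generator emulates the properties a gradient-based counter actually
interacts with, not photo-realism:

* background: white noise low-pass filtered at `background_scale` (12 px),
  scaled to amplitude 0.06 around mean 0.55 — smooth texture with no
  animal-scale structure;
* animals: anisotropic Gaussian blobs (axes 10 × 4 px, peak contrast 0.35
  below background, dark like a body against grass), orientation uniform
  on [0, 2π), centroids at least one body-length from the border and 24 px
  apart; rendered in closed form at pixel centres so a rotated instance
  involves no resampling (the invariance tests require this);
* light level: a global multiplier in (0, 1] applied to the finished
  scene;
* clutter (optional): long high-contrast streaks *not* recorded in the
  ground truth, emulating landscape structure that induces false
  positives;
* orientations may be drawn from a separate seeded stream so tests can
  re-draw every orientation with placements and background held fixed.

Default scenes are 256 × 256 px with 20 animals. What passing tests on
these scenes show is that the descriptor/classifier/grouping chain works
when its assumptions hold (isolated animals, smooth background, known
scale); what they cannot show is performance on real survey photographs,
with touching animals, shadows, vegetation structure and species
confusion. The evaluation module's statistics are designed exactly so that
a real count table can be dropped in
(`wildcount evaluate --counts counts.csv`).

## Evaluation statistics

With `D_i` the per-image difference between a counter and the reference
count over `N` images: RMS error `sqrt(1/N Σ D_i²)`, mean (signed) error
`1/N Σ D_i` (bias), totals, per-image means, and the coefficient of
variation (sample standard deviation over mean; the N−1 denominator is a
documented choice — at survey scale the distinction is negligible, but it
must be fixed for reproducibility). Detections are matched to true
centroids greedily by increasing distance within a radius (default half
the feature window), each side used at most once; TP/FP/FN follow, and TN
— reported but unused by precision/recall — counts the non-overlapping
animal-sized regions of the image not otherwise accounted for. The
under-count fraction `1 − automated/true` is regressed (OLS) on the mean
HSV value channel per image, after excluding over-counted images and
zero-truth images (fraction undefined; exclusions are logged). A constant
response returns slope 0 with R² = 0 rather than a NaN correlation.

## Numerical and degenerate-input choices

* Greedy matching breaks distance ties deterministically by detection then
  truth index.
* `fourier_encode_gradients` defines the phase of a zero gradient as zero
  (all modes zero), avoiding 0/0.
* Connected-component labelling, centroids and areas come from
  scipy.ndimage; a flood-fill oracle in the tests guards the counting
  semantics.
* All randomness flows from explicit `numpy.random.Generator` seeds; train
  + detect with a fixed seed is bit-reproducible.

## Problem sizes used by the test suite and acceptance script

Unit tests run a reduced configuration (8-px window, 2 rings, modes up to
2) on 96 × 96 scenes; the end-to-end checks and `scripts/acceptance.py`
use the full default configuration with 500 + 500 training samples from 25
scenes and 50 held-out evaluation scenes, plus a 6-level light sweep
(5 scenes per level) for the under-count regression. These sizes give
stable Monte-Carlo estimates (binomial standard error on recall at 1000
ground-truth animals is about 1%) while keeping a full run on one CPU in
the low minutes.

## Known limitations

* Counts, not positions, are the validated output: touching animals merge
  into one component by design (no overlap splitting).
* No scale handling — the survey's ground sampling distance is assumed
  constant, so the window size is a fixed parameter.
* The contrast pre-filter couples detection to absolute contrast; heavy
  vignetting or exposure gradients within one image would need a local
  normalisation stage the pipeline does not currently have.
* The published per-image count table for the real survey is an external
  download; without it the evaluation module can only be exercised on
  synthetic tables.
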