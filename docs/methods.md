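# Methods

This note records the models, conventions and design choices behind
`stvseg`, at the level of detail a maintainer needs to reproduce or modify
the pipeline.

## Coordinate and data conventions

All grids are indexed `(z, y, x)`, 0-based, with half-open index ranges.
Spacing and origin tuples follow the same order, in millimetres; the
default voxel size is `(dz, dy, dx) = (0.333, 0.114, 0.114)` mm, matching a
mechanically swept linear probe that is finely sampled in-plane and coarser
along the sweep. Physical coordinates are `origin + index * spacing`.
Intensities are min–max normalised to [0, 1] at load time; labels are
strictly {0, 1}. Contours live in their transverse plane as `(x, y)` mm
polylines, counter-clockwise when viewed from +z. A single stated
convention everywhere is deliberate: mixed index orders are the dominant
source of silent geometric bugs in this kind of code.

Reslicing samples native integer z-planes at evenly spaced indices
(endpoints always included) and never interpolates across slices, so label
slices stay binary and a dense reslice followed by restacking is exactly
the identity. Train/test splitting is done at the volume level so that no
slice of a held-out volume can appear in training.

## Synthetic phantom

The generator emulates the first-order appearance of a musculoskeletal
scan of the thumb base, not its physics:

* **Geometry.** A hypoechoic target sits between two bright curved bands
  (bone surrogates, a gentle parabola in x with a slow sinusoidal z
  modulation, kept ≥ 4 voxels clear of the target). The default target is a
  crescent — the region between two equal-radius discs whose centres are
  offset by a per-slice thickness that tapers smoothly (square-root
  profile) toward the z-extremes, emulating a synovial recess. An
  ellipsoid mode exists because its volume has a closed form, which makes
  it the natural oracle for voxelisation and mesh-volume checks.
* **Intensity.** Three echogenicity levels (target 0.15 < background 0.45
  < bone 0.85), multiplicative gamma speckle
  `I' = I * (1 + a (g - 1))`, `g ~ Gamma(k, 1/k)` with shape k = 3 and
  amount a = 0.35, and per-(z, x)-column attenuation shadows below bone
  (probability 0.15, width 0.6 mm, factor 0.5). Setting speckle and shadow
  to zero yields an exactly piecewise-constant image, which the tests use.
* **Second rater.** Per-slice boundary perturbation: the signed distance
  transform is shifted by a smooth zero-mean Gaussian random field
  (correlation length 6 voxels, amplitude scaled so ~95 % of displacement
  stays within the configured jitter), followed by optional uniform
  dilation or erosion for systematic over/under-contouring. Spatially
  correlated jitter is used because human raters disagree in smooth,
  regional ways, not pixel-by-pixel. Exactly one output component is kept
  per original slice component; slices eroded to nothing are left empty
  and reported in a warning list.
* **Datasets.** Per-volume draws jitter the target's centre (±3 % of the
  grid, y biased slightly downward) and scale (0.75–1.10); ranges are
  chosen so every draw fits the default grid with the required 2-voxel
  clearance. All randomness flows from one explicit seed per call.

What the phantom does *not* model: beamforming, frequency-dependent
attenuation, anisotropic speckle texture, neighbouring anatomy with
synovitis-like echogenicity, or rater fatigue. Passing tests therefore
demonstrate that the pipeline is correct and learnable on images with the
right gross structure — they say nothing about clinical performance, which
requires real scans.

## Segmentation networks

The U-Net and U-Net++ are implemented in NumPy on a small reverse-mode
autodiff core (im2col convolutions, 2×2 max-pooling, nearest-neighbour
upsampling, batch norm, channel concatenation). Every primitive's gradient
is tested against central finite differences; that test is the load-bearing
correctness argument for the whole training stack.

* **U-Net:** double-conv blocks (3×3, batch norm, ReLU), max-pool down,
  nearest-upsample + skip-concatenation up, 1×1 output head producing
  logits. `depth` counts resolution levels; input sizes must be divisible
  by 2^(depth−1).
* **U-Net++:** residual basic-block encoder (two 3×3 convs with identity
  skip, 1×1 projection on channel change — the ResNet-18 building block,
  with pooling instead of strided convs) and the nested dense skip decoder
  X[i][j] = H(concat(X[i][0..j−1], up(X[i+1][j−1]))). Deep supervision is
  off by default and only built on request. What a "modified" U-Net should
  modify is not specified anywhere authoritative; this package treats the
  architecture family as configurable rather than guessing.
* **Loss:** binary cross-entropy on logits plus soft Dice (ε = 1), the
  standard pairing for masks occupying a few percent of the image. BCE
  alone is slow to move the foreground class; Dice alone has noisy
  gradients early on.
* **Recipe:** the reference configuration is Adam, lr 1e-4, 100 epochs ×
  600 steps, batch 10 ("batch normalisation of 10" in the clinical
  description is read as batch size 10 alongside batch-norm layers — the
  phrase is ambiguous and this is the only reading consistent with both
  words). Augmentation draws random flip/rotation(≤20°)/translation(≤20 %)
  /zoom(≤20 %) combinations, applied identically to image and mask, the
  mask re-binarised at 0.5 after linear interpolation.
* **Scaled-down profile** (`TrainConfig.scaled_down()`): depth-2 U-Net,
  8 base filters, 64×64 inputs, batch 10, ≤ 10 epochs of full passes,
  lr 5e-3. The learning rate was picked from short pilot runs as the
  fastest stably converging setting at this model size; with it the
  phantom study (≈ 280 training slices) trains in about two minutes on one
  CPU core and reaches held-out per-slice Dice above 0.9. The scaled
  profile trains *without* augmentation: synthetic data is unlimited, so
  the variance augmentation adds buys nothing and slows short runs.
  Residual failure mode: slices at the target's z-extremes where the
  crescent thins below one voxel are sometimes missed entirely — the same
  slices a human would find ambiguous.
* **Inference:** probability ≥ threshold (default 0.5); images that do not
  match the model input size are edge-padded/cropped with the inverse
  applied to the mask. Inference is deterministic; training is
  deterministic given the three seeds (weights, shuffling, augmentation) —
  there is no hidden backend nondeterminism in a pure NumPy stack.

## Surface reconstruction

Masks → contours → mesh → volume:

1. **Extraction:** marching squares at iso-level 0.5 (sub-pixel, reduces
   staircase bias in surface-distance metrics relative to pixel-edge
   tracing); the mask is zero-padded by one pixel first so edge-touching
   foreground still closes. Components under 3 points are dropped.
2. **Single-structure assumption:** one contour per slice, the largest by
   enclosed area (ties: first in scan order). The synovial region is
   treated as one structure; smaller components are dropped with a
   warning, multi-object topology is out of scope.
3. **Resampling:** n points (default 64) equally spaced by arc length from
   the original start point. 64 points keep the cylinder discretisation
   error below 0.2 % while keeping the exhaustive alignment cheap.
4. **Correspondence:** the cyclic offset minimising the sum of squared
   point distances, searched exhaustively over all n offsets with
   orientation preserved — the simplest twist-minimising rule, and one an
   independent brute-force check can confirm. Offsets accumulate down the
   stack.
5. **Stitching and caps:** adjacent rings joined as quad strips split into
   triangles; first and last rings capped by triangle fans to their
   centroids (adequate for star-shaped cross-sections; a strongly
   non-convex end slice could self-intersect, which is accepted and
   documented rather than smoothed away). With CCW rings the construction
   gives consistently outward normals and a watertight mesh, verified by
   edge-incidence counting (every edge on exactly two faces) and the Euler
   characteristic V − E + F = 2.
6. **Volume:** |Σ det(v₀,v₁,v₂)|/6 over faces. Exact for polyhedra,
   invariant to rigid motion to rounding; refusing non-watertight input is
   an error contract, not a repair step.

Interior slices with empty masks are bridged by linearly interpolating the
two flanking (aligned) rings by default; with interpolation off the stack
splits at the gap and the largest sub-surface volume is reported. Empty
slices at the ends are dropped. No mesh smoothing is applied anywhere — it
would bias volumes, which are the quantity of interest.

## Evaluation metrics

* 2D records per slice: overlap metrics from pixel counts; distances
  between extracted sub-pixel boundaries in mm; area percent difference
  from foreground pixel areas.
* 3D overlap pools per-slice confusion counts (averaging and summing give
  identical ratios — an identity the tests assert). Pooled counts, not
  voxelised meshes, are the definition; mesh-vs-voxel volume agreement is
  kept as a separate property check.
* Distances are always in physical mm. MSD is the symmetric mean of the
  two directed mean nearest-neighbour distances; HD the maximum of the two
  directed maxima. Small point sets use exact all-pairs distances, larger
  ones a k-d tree.
* Signed distances give each predicted boundary point the sign of its
  position relative to the reference interior — positive outside
  (over-segmentation) by default, configurable, since the opposite
  convention is also in circulation. Interior membership is tested by
  bilinear (2D) or trilinear (3D) sampling of the reference mask at the
  point's physical position. The signed HD is the signed distance of
  maximal magnitude.
* Percent difference uses the manual measurement as denominator:
  signed = (measured − manual)/manual × 100, absolute = |signed|.
  Symmetric-mean denominators exist; the asymmetric form is used because
  the manual segmentation is the declared gold standard.
* 0/0 conventions, flagged as degenerate: both masks empty → overlap
  metrics 100 %; empty prediction vs nonempty reference → precision 0 %.
  Distance and percent-difference fields are NaN when a boundary does not
  exist. Degenerate cases arise only with synthetic or pathological data;
  studies without any synovitis are excluded upstream.

## Statistics

Paired comparisons run Shapiro–Wilk on the differences at α = 0.05;
normal-looking differences take the two-tailed paired t-test, others the
Wilcoxon matched-pairs signed-rank test (zeros dropped — the classic
variant; exact null distribution for small tie-free samples, normal
approximation with continuity correction otherwise, via SciPy). The gate
decision, the normality p-value and the sample size are always recorded in
the result, since which test fired is part of the finding. All-zero
differences short-circuit to an "identical samples" result (p = 1,
flagged); constant nonzero differences have a divergent t statistic and
are reported as p = 0 with no normality p. Under a pure-noise null the
gated procedure's type-I rate is calibrated (the acceptance checks measure
it at ≈ 0.05 over 1000 seeded replicates).

Bland–Altman analysis orients differences as (method − manual reference),
bias = mean difference, SD with n−1 denominator, limits of agreement at
bias ± 1.96 SD. No confidence intervals on the limits are computed.

## Problem sizes

The scaled-down study used throughout testing and in
`scripts/acceptance.py`: 40 phantoms of 40×64×64 voxels, 10 slices each
(≈ 280 training / 20 validation slices, 10 held-out volumes), depth-2
8-filter U-Net, ≤ 10 epochs. These sizes are the package's CPU-sized
defaults; the clinical-scale recipe remains available through the
configuration objects.

## Known limitations

* One structure per slice; branching or merging synovial recesses are not
  reconstructed.
* Centroid-fan caps assume star-shaped end cross-sections.
* The phantom's realism is qualitative (hypoechoic target, bright bands,
  shadows, speckle); no intensity statistics from real scans were
  available to calibrate against.
* The NumPy networks are CPU-bound and meant for correctness and
  small-scale studies, not for training at clinical scale.
* Volume-level significance tests assume independent volumes; repeated
  scans of the same joint over time would need repeated-measures models,
  which are out of scope.
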