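# stvseg

Automatic **synovial tissue volume (STV)** estimation from 3D ultrasound of
the first carpometacarpal (CMC1, thumb-base) joint. Synovitis — inflammation
and hypertrophy of the joint's synovial membrane — appears as a *hypoechoic*
(dark) region between the bright bone surfaces of the trapezium and first
metacarpal, and its volume is a quantitative marker of osteoarthritis
activity. Manual slice-by-slice contouring of one 3D scan takes an expert
10–20 minutes; this package automates it for researchers working on
musculoskeletal ultrasound and for method developers who need a fully
reproducible, dependency-light reference pipeline.

## Method

1. **Slice segmentation.** A 3D scan (voxel size 0.114 × 0.114 × 0.333 mm)
   is resliced into transverse 2D planes. A 2D U-Net (or U-Net++ with a
   ResNet-18-style residual encoder) maps each plane to a probability map,
   thresholded at 0.5 into a binary mask. Training uses Adam
   (lr 1 × 10⁻⁴, 100 epochs × 600 steps, batch 10) with random flips,
   rotations ≤ 20°, translations ≤ 20 % and zooms ≤ 20 %; a scaled-down CPU
   profile (depth-2 U-Net, 8 base filters, lr 5 × 10⁻³, ≤ 10 epochs) trains
   in minutes. The networks are implemented in pure NumPy with a small
   reverse-mode autodiff core whose gradients are verified against finite
   differences.
2. **Surface reconstruction.** Per-slice masks are turned into sub-pixel
   boundary contours (marching squares at iso-level 0.5), resampled to *n*
   equally spaced points, brought into cyclic correspondence between
   adjacent slices by exhaustive least-squares offset search, stitched into
   triangle strips, and capped at both ends with centroid fans. The result
   is a watertight genus-0 mesh; the STV is its enclosed volume
   V = |Σ_faces det(v₀, v₁, v₂)| / 6 (divergence theorem), in mm³.
3. **Evaluation.** Per-slice confusion counts give precision, recall,
   accuracy and DSC = 2TP/(2TP+FP+FN); 3D overlap metrics pool the
   per-slice counts. Boundary agreement uses mean surface distance and
   Hausdorff distance in mm, plus signed variants (positive outside the
   reference). Area/volume percent difference is
   (measured − manual)/manual × 100.
4. **Statistics.** Paired method comparisons are gated by a Shapiro–Wilk
   test on the differences (α = 0.05): paired *t*-test if normal, Wilcoxon
   matched-pairs signed-rank otherwise. Agreement is summarised by
   Bland–Altman bias and 1.96 · SD limits of agreement.

Because clinical scans cannot be shipped, a seeded **synthetic phantom**
module generates ultrasound-like volumes — two bright curved bone bands
with attenuation shadows, a hypoechoic crescent (or ellipsoid) target with
exact voxel ground truth, multiplicative gamma speckle — plus a simulated
second rater (smooth boundary jitter and systematic dilation/erosion).

## Worked example

```python
from stvseg.phantom import (PhantomParams, RaterPerturbation,
                            generate_phantom, simulate_second_rater)
from stvseg.volume import reslice_label
from stvseg.surface import masks_to_surface
from stvseg.metrics import evaluate_pair_3d

vol, label = generate_phantom(PhantomParams(seed=7))
stack = reslice_label(label, label.shape[0])
surface, stv, _ = masks_to_surface(stack, stack.images)
print(f"voxel-count STV: {label.volume_mm3():.2f} mm^3")
print(f"mesh-enclosed STV: {stv:.2f} mm^3 ({stv/1000:.5f} cm^3)")

rater2, _ = simulate_second_rater(label, RaterPerturbation(jitter_voxels=1.5, seed=1))
r2_stack = reslice_label(rater2, rater2.shape[0])
r2_surface, r2_stv, _ = masks_to_surface(r2_stack, r2_stack.images)
rec = evaluate_pair_3d(r2_stack.images, stack.images, (0.114, 0.114),
                       r2_surface, surface, r2_stv, stv, gt_label=label)
print(f"rater-2 vs rater-1: DSC {rec.dsc:.1f}%, MSD {rec.msd:.3f} mm, "
      f"HD {rec.hd:.2f} mm, sMSD {rec.signed_msd:+.3f} mm, VPD {rec.avpd:.1f}%")
```

prints

```
voxel-count STV: 32.68 mm^3
mesh-enclosed STV: 32.17 mm^3 (0.03217 cm^3)
rater-2 vs rater-1: DSC 97.3%, MSD 0.063 mm, HD 0.38 mm, sMSD +0.001 mm, VPD 0.6%
```

The mesh volume agrees with voxel counting to 1.6 % on this phantom; the
simulated second rater's smooth jitter changes the volume by under 1 % while
moving the boundary by 0.06 mm on average — the kind of disagreement the
signed metrics and Bland–Altman analysis are designed to expose.

The same workflow is available from the shell:

```sh
stvseg phantom --n 10 --seed 0 --out data/
stvseg run-all --scaled-down --seed 0 --out runs/demo
stvseg reconstruct --mask data/vol000_label.nii.gz --out vol000.obj
```

`run-all` writes per-slice and per-volume metric tables
(`reports/metrics_2d.csv`, `reports/metrics_3d.csv`), a 2D-vs-3D paired
comparison (`reports/comparison.csv`) and Bland–Altman agreement data for
the predicted vs manual volumes.

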