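# Methods

## Coordinate and angle conventions

Pixels are 0-based `(row, col)`, origin top-left; pixel spacing is in mm per
pixel. Angles are in degrees, counterclockwise as displayed (the row axis
points down), with 0° on the ray from the LV cavity center through the
anterior RV insertion point. The reference is configurable; it follows the
common bull's-eye display convention but is not uniquely fixed by clinical
practice. All angular bins are half-open `[start, end)`, so a boundary angle
belongs deterministically to the bin it starts.

## Partition model

The AHA model assigns 6 basal (60°), 6 mid (60°) and 4 apical (90°)
segments plus the apex. The refined partition divides every non-apex segment
into three equal sub-segments ordered by increasing angle (20° basal/mid,
30° apical), yielding 49 regions; the apex is never subdivided because it has
no cavity to anchor radial geometry. Region ids are canonical: basal
sub-segments 1–18, mid 19–36, apical 37–48, apex 49; in 17-mode the region
id equals the AHA segment id, and every 49-mode bin nests inside exactly one
17-mode bin with the same segment id. Mapping of segment numbers to named
walls (anteroseptal, inferolateral, …) is display metadata only and is not
used by any computation.

## Wall thickness

Thickness is radial: from the cavity center a ray at angle θ is cast and
the thickness at θ is the distance in mm between the first endocardial
crossing and the first epicardial crossing at or beyond it. The
first-crossing rule makes the measure robust to small contour wiggles that
produce extra intersections. Rays are sampled densely — default step 1°,
configurable; a step equal to the bin width reproduces one-ray-per-bin
behaviour — and averaged within each bin; slices sharing a level pool their
samples. Anisotropic spacing is handled by measuring in physical
coordinates (contours scaled to mm before rays are cast). Rays that miss a
contour are skipped with a warning rather than poisoning the regional mean.

The apex has no cavity, so the radial measure is undefined there; apex
thickness is reported as twice the maximal inscribed-disc radius of the
filled epicardial polygon and flagged approximate in the report
(`ThicknessReport.approximate_regions`).

## Severity grading

Bands: score 0 for RWT < 15 mm, 1 for 15–20 mm inclusive, 2 for
(20, 25] mm, 3 above 25 mm. The closed/open edges are deliberate:
20.0 mm is mild and 25.0 mm is moderate. The scorer is monotone and the four
bands tile `[0, ∞)` with no gaps or overlaps.

## Networks and training

No deep-learning framework is assumed: `lvhquant.nn` is a small numpy
engine (im2col convolution, batch normalization, 2×2 average/max pooling
with floor division on odd sizes, dense, dropout, softmax; manual
backpropagation; SGD/Adam/Adamax/RMSprop). Every backward pass is verified
against finite differences in the test suite.

**Segmenter.** A U-Net of configurable depth (3, 4 or 5 blocks per side,
depth 4 the default): each encoder block is two zero-padded conv–BN–ReLU
layers followed by 2×2 average pooling (average pooling gives smoother
probability maps than max pooling); the decoder mirrors it with
nearest-neighbour upsampling, a channel-halving convolution and skip
concatenation; a 1×1 convolution and per-pixel softmax produce a two-class
(myocardium / background) map the size of the input. The loss is
1 − soft-Dice on the myocardium channel. Defaults: Adam, learning rate 1e-2,
batch 4. The cavity is recovered as the hole in the predicted mask, so endo-
and epicardial contours come from one network. Training keeps the
best-validation parameter state.

**Classifier.** The reference sub-segment classifier is the 25-layer CNN
described in the README; the shape trace is computed analytically, with
convolution parameters `(kh·kw·Cin + 1)·Cout`, batch norm `2·C` and dense
`(Nin + 1)·Nout`. The later convolutions use an explicit zero pad of 2
(maps grow by 4: 128 → 130, 65 → 67, …) and pooling floors odd sizes
(67 → 33, 35 → 17, 19 → 9); the flattened 9·9·512 features feed
dense-128 → dropout 0.3 → dense-16 → softmax. The softmax head carries its
own (16+1)·4 output projection, reported as its 68 parameters in the trace.
A sub-segment is encoded as the full normalized slice with everything
outside the region's myocardial sector zeroed, padded square, resized, and
replicated to three channels — this keeps the fixed-size whole-image input
contract while localizing the evidence; a crop or a thickness-vector input
would be defensible alternatives. Classifier labels are the threshold
scores of the measured regional thickness, making the network a learned
surrogate of the threshold rule. Defaults: Adamax, learning rate 1e-3,
batch 4, 70 epochs, stratified 70/10/20 split.

## Synthetic phantoms

Each phantom slice is an annulus around a circular cavity: the endocardium
is a circle of `cavity_radius` and the epicardium at angle θ lies
`thickness_profile(θ)` beyond it, so per-angle thickness is closed-form and
regional truth is the profile mean over each bin. Only the epicardium
carries angular variation — this keeps the truth analytic. Truth contours
are emitted at 1° vertex resolution, a factor 20 below the narrowest bin,
so polygon discretization error is far below the measurement tolerance.
The apex is a filled disc (no cavity). Intensities mimic balanced-SSFP
contrast (bright blood pool 0.9, myocardium 0.45, background 0.05 in
arbitrary units); boundaries are rendered with a one-pixel analytic
partial-volume blend, as in-plane voxel averaging does in MR, which is what
lets sub-pixel wall differences remain visible to the classifier; noise is
additive Gaussian clipped to [0, 1] (no MR physics is claimed — no coil
shading, banding, papillary muscles or motion).

Cohorts draw a severity class per region from a configurable mix (default
0.55/0.20/0.15/0.10, an LVH-enriched case load where most regions are
normal) and a target thickness uniformly within that class's band (normal
6–14.5 mm, mild 15–20, moderate 20.1–25, severe 25.1–32); level profiles
are the resulting piecewise-constant functions over the bins, so ground
truth realizes the requested mix exactly by construction. Identical spec
and seed give bit-identical output.

What passing on phantoms does **not** show: robustness to papillary
muscles and trabeculae (the main real-world cause of endocardial error),
through-plane effects, scanner contrast variation, or imperfect expert
contours. Phantom results validate the geometry, measurement and learning
machinery, not clinical performance.

## Problem sizes for the learning runs

The in-package training runs are deliberately small, chosen as the smallest
cohorts on which the learning behaviour is meaningful: segmentation trains
on 40 noiseless 96×96 phantom slices (depth-4 U-Net, 8 base filters, 15
epochs) and is judged by held-out hard Dice; classification trains on a
30-phantom cohort with a balanced severity mix, 24 sector-encoded ring
regions per phantom at 64×64 input and a width-reduced (factor 0.25)
variant of the reference topology, 70 epochs. Pixel spacing stays at the
clinical 1.25 mm in both runs; coarser spacing was found to quantize away
the sub-pixel wall differences that separate adjacent severity bands at
their boundaries. The full-width 256×256 architecture is constructed and
shape-verified but not trained at desk scale.

## Numerical choices and edge cases

- Min–max normalization is per slice (scanners differ per acquisition); a
  constant image maps to all zeros instead of raising, so blank
  background slices pass through.
- `dsc(∅, ∅) = 100` by convention (two empty masks agree perfectly).
- Hausdorff distance is point-to-segment, not point-to-vertex, making it
  stable under re-discretization of the same curve; at 1° contour
  resolution it is stable to well below 0.01 mm.
- Undefined precision/recall (zero denominator) is reported as 0 with a
  `degenerate` flag — needed for degenerate splits on tiny cohorts.
- Multiple mask components: the largest is kept with a warning; a non-apex
  mask without a cavity is an error rather than a silent apex.
- Slice levels, when unlabeled, are assigned by contiguous thirds
  (base → apex, ties to the more basal level) after trailing no-cavity
  slices are labeled apex; explicit labels always win. This is a stand-in
  for the radiologist's slice selection.
- Whether multiple slices per level should be averaged or one
  representative slice picked is genuinely open; averaging was chosen as
  the lower-variance option.
- Landmark detection from images is not claimed: the cavity centroid is
  computed from the mask, and insertion angles come from an override, a
  supplied pair, or an RV-contact-arc heuristic when an RV label exists.

## Known limitations

- The RV-insertion heuristic needs an RV label; fully automatic insertion
  detection from raw intensities is out of scope.
- Apex thickness via the inscribed-disc proxy is not comparable to the
  radial measure and is flagged approximate.
- The depth study (underfitting at depth 3, overfitting at depth 5) cannot
  be reproduced on phantoms: analytic annuli are easy enough that all
  depths fit them, so `depth_study` reports the numbers without asserting
  a direction.
- Trained-model outputs are compared against thresholds, never for exact
  equality: per-run determinism holds on one machine, but bitwise
  reproducibility across BLAS builds is not guaranteed.
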