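# Methods

## Problem setting

A whole agar-filled Petri dish is photographed from a fixed distance in
transmitted light. Adult *C. elegans* appear as thin, dark, smoothly curved
objects (here on the order of 100–160 px long and ~9 px wide at full
resolution) on a bright agar disc; the dish rim is a dark, contrast-rich
annulus; trapped air or gas in the agar forms dark near-circular blobs that
are the dominant confuser. The task is to output one instance mask per
worm, the worm count, and detection-quality metrics against reference
masks.

## Dish localization

The dish is found from a single horizontal scan line through the vertical
image center. The line is smoothed with a width-5 moving average; an edge
is any position where the absolute luminance difference across a ±3 px
window exceeds a threshold, by default 25 % of the image's dynamic range
(the threshold is a free parameter because plate illumination varies). The
centers of the first and last super-threshold runs are the left/right dish
edges; the circle's center is their midpoint (at the scan line's height)
and the radius is half their distance. If only one run is found, the
missing edge is clamped to the image border; if none is found, a
"dish not found" error is raised and callers may fall back to a
whole-image circle. When masking, the radius is shrunk by a margin
fraction (default 0.05) so the rim band — a reliable source of false
positives — is blackened along with the outside. Masking is idempotent and
leaves interior pixels bit-identical.

The scan-line approach assumes the dish edge crosses the central row; it
deliberately avoids full circle-fitting (e.g. Hough transforms), which the
fixed acquisition geometry does not require.

## Tiling

Full-resolution plates are processed in tiles of 820 × 821 px with 25 %
overlap. The stride is floor(tile × (1 − overlap)) = 615 px in both axes;
the last tile of each axis is clamped to the image border rather than
padded, preserving the exact tile size at the cost of extra overlap in the
final row/column. For a 3280 × 2464 plate this yields a 5 × 4 grid of 20
tiles whose union covers every pixel. The fractional stride implied by a
25 % overlap of an odd 821 px tile is floored; this choice is recorded here
because either rounding direction satisfies the coverage invariant.

Detections made in tile coordinates are translated back to the full frame
and de-duplicated greedily by descending score, dropping any detection
whose IoU with an already-kept one reaches 0.3 (mask IoU when both carry
masks, box IoU otherwise) — the same threshold as the per-class NMS, since
cross-tile duplicates are the same kind of redundancy. In the tiled
classical route, segments touching a tile border that is not an image
border are discarded: the overlap (205 px nominally) exceeds one worm
span, so such fragments are always covered whole by a neighboring tile.

## Classical segmentation chain

All stages are deterministic; there is no randomness anywhere in the chain.

1. **Bilateral filter** (window 9 px, range sigma 10 gray levels, spatial
   sigma 5 px): denoises while preserving the worm/agar edges. The range
   parameter is interpreted as the filter's range (color) sigma in 8-bit
   gray levels.
2. **Grayscale** via Rec.709 luma weights (0.2125, 0.7154, 0.0721).
3. **Gaussian adaptive threshold** (window 71 px, offset 4): a pixel is
   foreground iff its value is below the Gaussian-weighted local mean minus
   4. The polarity (dark = foreground) encodes the brightfield convention;
   a constant image therefore produces no foreground at all.
4. **Morphology**: closing then opening with a 3 × 3 cross (disk of radius
   1). Closing fills pinholes inside worm bodies; opening removes isolated
   specks. The kernel is our choice; the operations' order is fixed.
5. **Connected components** with 8-connectivity (the common blob-detector
   default).
6. **Blob filter**: a component is removed iff its descriptors fall inside
   *all* of: area ∈ [0, 700] px², convexity ∈ [0.3, 1], circularity > 0.2,
   inertia ratio ∈ [0.2, 1]. The ranges describe objects to *remove*
   (round bubbles); adult worms escape the conjunction through their area
   (> 700 px²) and their elongation (inertia ratio ≪ 0.2). Descriptors
   follow standard conventions: circularity = 4πA/P² with the Crofton
   perimeter estimate (circularity can slightly exceed 1 for tiny
   components — a discretization artifact, not an error), convexity =
   area / convex-hull area, inertia ratio = minor/major eigenvalue of the
   inertia tensor.
7. **Minimum-size filter** on bounding boxes: removed iff box area
   < 700 px² AND shorter edge < 24 px. The conjunction is the literal
   reading of the rule; a disjunctive variant is available via
   `SizeFilterParams.combine="or"`.
8. **Worm area band** (default 250–5000 px² of mask area): stands in for
   the visual-inspection step of semi-automatic annotation — components
   shaped like worms but far from adult size are dropped. It also removes
   the ring-shaped threshold artifact that the dish-mask boundary leaves.

Adding any filter can only remove components, so mask counts decrease
monotonically along the chain.

## Detection post-processing

For externally produced detections the chain applies, in order: background
label removal, a confidence floor of 0.92, per-class greedy NMS at IoU
0.3, a top-100 cap by score, and the same minimum-size filter as above.
Greedy NMS keeps the highest-scoring remaining detection and suppresses
everything overlapping it at or above the threshold; ties in score are
broken by lower id, making the whole chain deterministic. Stage-by-stage
input/output counts are exposed (`return_stage_counts=True`) and logged so
the attrition is auditable. The detector's training recipe (anchors,
ratios, proposal limits, learning schedule, warp size, backbone) is
serialized verbatim by `emit_mrcnn_config`; the `rpn_anchor_scale` field is
an opaque passthrough of the upstream framework and is not interpreted.

## Evaluation

Matching is greedy by descending confidence: each prediction takes the
unmatched ground truth of highest IoU provided IoU ≥ τ; each ground truth
is used at most once. This assignment order is the COCO/VOC convention; the
IoU rule and FN/FP accounting alone do not pin it down, so the convention
is our documented choice. AP uses all-points interpolation: precision is
replaced by its running maximum from the right and integrated over recall
increments. Average mask IoU is reported over matched pairs only; averaging over all
prediction/best-ground-truth pairs was considered and rejected, as it
conflates localization quality with detection errors. Metrics
with zero denominators are reported as NaN with a warning rather than
raising, so empty plates survive batch runs.

## Synthetic plate generator

The generator emulates exactly the features the pipeline keys on:

- geometry: bright agar disc (gray level 200) with a dark rim annulus (30)
  on a near-black background (5); default dish nearly fills the short image
  axis;
- worms: midlines are unit-step random-heading walks, heading increment ~
  Normal(0, 0.25 rad); bodies are unions of discs along the midline with
  the half-width (default 4.5 px) tapering toward head and tail; level 70.
  Length defaults (100–160 px) are calibrated so that even tightly curled
  adult masks exceed the 700 px² / 24 px minimum-size filters, matching
  the intended operating regime in which those filters remove debris, not
  worms. Worms are steered back toward the center whenever a step would
  leave the usable region, which is shrunk by an 8 % containment margin so
  the default dish-mask shrink (5 %) never clips a ground-truth pixel;
- worm load: 25 per plate by default (the reported average on real plates
  is ~24.5); tests and the acceptance run use 8 separated worms on 640 px
  plates for speed;
- artifacts: 6 near-circular blobs (radius 5–12 px, level 90) per plate,
  never touching worms so ground truth stays uncorrupted;
- noise: additive Gaussian (sigma 3 by default), then rounding/clipping to
  8-bit.

Identical configurations (including the seed) yield bit-identical images
and masks. What the generator does **not** model: optics (vignetting,
point-spread blur, JPEG compression artifacts), illumination gradients,
agar texture, condensation, eggs and larvae, and worm motion across
frames. Passing tests on synthetic plates therefore demonstrate the
correctness of the pipeline's logic — thresholding polarity, shape
discrimination, bookkeeping, metric arithmetic — not field performance on
real microscopes, which depends on the unmodeled nuisances.

## Problem sizes and numerical choices

The test and acceptance workloads use 640 px plates (20 plates × 8 worms
for parameter recovery), 1000 random instances of up to 20 boxes for the
NMS/matching oracle comparison, and 100 random rankings for the AP oracle;
these sizes make the whole suite run in a couple of minutes on one CPU
while still exercising every branch. The AP oracle integrates the
precision envelope on a dense (10⁵-point) recall grid, so agreement is
asserted to 10⁻³. Degenerate inputs are handled explicitly: empty masks
are unrepresentable (construction fails), zero ground truths make AP an
error, zero predictions make precision NaN-with-warning, an even adaptive
window or non-odd morphology kernel is rejected.

## Known limitations

- Crossing or touching worms merge into one component (classical route) or
  one detection; splitting them needs temporal or learned cues.
- The dish detector assumes one dish whose edge crosses the central row.
- The classical route has no confidence notion; all its detections carry
  score 1.0, which makes its PR curve degenerate (a single operating
  point).
- Real-image performance of the classical chain depends on illumination
  uniformity; the defaults were chosen for the synthetic conditions above
  and for plates captured under controlled, standardized lighting.
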