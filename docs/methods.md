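# Methods

`nucseg` segments epithelial nuclei in H&E-stained breast-cancer
histopathology tiles with a multiscale, multimarker marker-controlled
watershed. This note documents the model, its parameters and defaults, the
numerical choices, what the synthetic generator does and does not emulate,
and the known limitations.

## Image formation and stain separation

Bright-field H&E imaging follows the Lambert–Beer law: per detection
channel *k*, transmitted intensity is `I_k = I0_k · 10^(−Σ_s M[k,s]·c_s)`,
with `M` the per-channel absorption coefficients of each stain and `c_s`
the local stain concentration. Optical density `OD = −log10(I/I0)` is
therefore linear in the concentrations and a per-pixel 3×3 solve separates
hematoxylin from eosin. Defaults:

* Stain matrix: the standard published H&E absorption vectors
  H ≈ (0.65, 0.70, 0.29), E ≈ (0.07, 0.99, 0.11), each column normalized to
  unit length; the residual third column is the normalized cross product of
  the two with negative components clipped to zero (keeps the matrix
  non-negative and invertible). Configurable per run for re-stained or
  re-scanned material.
* OD clamp: intensities are floored at `I0/255` before the log so
  saturated-black pixels map to the finite ceiling `log10(255) ≈ 2.41`.
* The "hematoxylin image" is the hematoxylin-only RGB image re-rendered
  through the forward model from the hematoxylin concentration alone, then
  collapsed to grayscale with Rec.709 luminance weights (nuclei dark). The
  raw concentration map is also exposed
  (`stain.hematoxylin_concentration`) for users who prefer it.

## Multiscale morphological simplification

At scale *n* (disk-SE radius in pixels) the hematoxylin image is simplified
by opening by reconstruction with disk(*n*) (removes bright clutter),
closing by reconstruction with disk(*n*) (removes dark clutter smaller than
the SE — this is also what suppresses lymphocytes and junk smaller than the
scale), then a plain morphological closing with disk(round(*n*/2)) to clip
thin protrusions. The final closing is a plain (non-reconstructive)
closing: it is meant to simplify the outline, and a reconstructive closing
would undo exactly the simplification it is there to produce.

The scale set defaults to n ∈ {10, …, 18} px, the expected range of nuclear
minor semi-axes at ×40 magnification (0.25 µm/px). A dark object whose
minor semi-axis is below *n* is erased by the closing at that scale, so
each scale is sensitive to nuclei at and above its own size; running all
scales and merging recovers the full size range.

Conventions: 8-connectivity for all minima/component operations (with
4-connectivity for complements where duality requires it), replicate
("nearest") border padding for the grey-morphological operators, and exact
Euclidean disk footprints (the half-radius SE rounds to the nearest
integer).

## Fast radial symmetry transform and markers

The orientation-only FRST accumulates one unit vote per strong-gradient
pixel at `p − round(r·ĝ)` — the dark-polarity target, since hematoxylin
nuclei are dark and their boundary gradients point outward. Per radius, the
vote image is clamped at κ, normalized, raised to the radial-strictness
power α, and smoothed with a Gaussian of σ = 0.5·r; radii are combined by
averaging over r ∈ {n, …, 2n}. Constants not fixed by the method itself are
the transform's published defaults — α = 2, κ = 9.9, gradient floor 5 % of
the maximum Sobel magnitude, Gaussian factor 0.5 — and all are exposed in
the config. The map is negated and min–max normalized so nucleus centers
are *minima* in [0, 1]; FRST foreground markers are its extended regional
minima with depth h = 0.4.

The second marker type, aimed at elongated or asymmetric nuclei where the
symmetry assumption fails, takes the regional minima of the preprocessed
image directly, discarding components that touch the frame border or exceed
the maximal nucleus area 4·n²·π (both are background plateaus, not nuclei).

Background marker: every foreground marker is assumed to mark a nucleus of
maximal radius 2n; the markers are dilated by disk(2n) (implemented as an
exact Euclidean distance threshold) and the morphological skeleton of the
complement is the background marker. If the dilation covers the frame the
scale/marker combination is skipped as too dense.

Watershed: minima are imposed at the marker pixels on the Sobel gradient
magnitude of the preprocessed image via the standard
reconstruction-by-erosion construction, and the watershed floods one region
per marker (ridge pixels and the background-grown region are labeled 0).
Flooding ties are resolved deterministically by the queue order of the
flooding implementation, so repeated runs are bit-identical.

## Rule-based region rejection and ellipse standardization

Four features per watershed region, measured on the preprocessed image at
the region's own scale (the image whose gradient defined the region):

| feature | definition | accepted range |
|---|---|---|
| solidity *s* | area / convex-hull area | (0.875, 1) |
| boundary saliency *l* | median intensity in a 3-px outer band − median in a 3-px inner band | (20, 255) |
| mass displacement *d* | ‖centroid − inverse-intensity-weighted centroid‖ / moment-ellipse minor axis | [0, 0.08] |
| area | pixel count | [n²π, 4n²π] |

Interval senses are enforced exactly as written. Inverse-intensity weights
are `256 − I` (bounded, monotone decreasing, never divides by zero); the
inner/outer bands come from erosion/dilation of the region mask by
disk(3) — "tight band" is not quantified by the rejection rules themselves,
and 3 px is configurable. A region whose outer band is empty (frame-filling
region) has undefined saliency and is rejected. Survivors are standardized
as moment-matched ellipses (same second central moments; semi-axes
`2·sqrt(λ)` of the covariance eigenvalues), with the source region's
solidity attached as the fitness for merging. The mass-displacement
normalizer is the moment-ellipse minor axis, which coincides with the
fitted ellipse's minor axis under this fit.

## Cross-scale merging

Candidates from all scales and both marker types enter one pool. Conflict
is measured on the rasterized ellipse interiors with the containment
overlap `OV(Xi,Xj) = |Xi∩Xj| / min(|Xi|,|Xj|)`; pairs with OV strictly
above T_h = 0.2 are adjacent (at or below: merely "touching", both may
survive). Resolution is greedy: accept the highest-fitness unresolved
candidate, reject its neighbors, repeat. Ties are broken by larger area,
then lower scale, then FRST before minima markers, then input order — the
published algorithm is silent on ties, and a total order guarantees
determinism. Accepted regions may overlap by up to OV = 0.2; when a single
label map is rasterized, earlier-accepted (higher-fitness) regions keep the
contested pixels.

## Evaluation protocol

A ground-truth nucleus is a true positive when its best Dice
`D = 2|X∩Y|/(|X|+|Y|)` against any automatic region is ≥ 0.2, else a false
negative; matching is per-ground-truth without exclusivity. Sensitivity is
TP/(TP+FN). Object-level PPV is the fraction of automatic regions whose
best Dice against any ground-truth nucleus reaches the cutoff — on
synthetic data this replaces expert labeling of sampled regions, and it is
a protocol surrogate, not the same measurement. Median Dice is reported
over matched pairs (the Dice distribution is left-skewed); a variant
including unmatched nuclei as zeros is reported alongside
(`median_dice_all`). Mean nuclear area is the mean of π·a·b over accepted
ellipses; a linear correction (slope, intercept) fitted by least squares on
paired automatic/manual MNA values over a training image set corrects the
systematic underestimation caused by small junk segmentations and
under-segmentation of large nuclei.

## Synthetic tile generator

The generator writes hematoxylin/eosin concentration fields and renders
them through the same Lambert–Beer forward model the unmixing inverts, so
forward/inverse consistency is testable end to end. It emulates: nucleus
geometry (ellipses, minor semi-axes 10–18 px by default, mean area near
900 px), controlled clustering (touching pairs placed at 0.97× the sum of
directional radii; contested pixels assigned to the nucleus in whose
normalized frame they lie deeper), multiplicative chromatin texture, a
marginalized-chromatin mode (dim core, dark rim), eosin stroma with smooth
texture and fiber strokes, and distractors (lymphocyte-like dark disks of
radius 3–7 px, junk particles of radius 1.5–4 px). Difficulty presets:

* `easy` — well-separated nuclei, faint texture, no distractors;
* `medium` — 30 % clustered, moderate texture, 12 lymphocytes + 8 junk;
* `hard` — 50 % clustered, marginalized chromatin, 20 lymphocytes + 12 junk;
* `bimodal` — two size populations (minor semi-axes 10–11 and 17–18 px)
  for multiscale-vs-single-scale comparisons; both populations sit inside
  the method's working range, since a nucleus with minor semi-axis below
  the smallest scale is unrecoverable at every scale by construction.

It does **not** emulate tubule architecture, stain variability across
laboratories, out-of-focus or stitching artifacts, necrosis, or heavy
lymphocytic infiltration. Passing the synthetic end-to-end checks therefore
demonstrates that the pipeline implements the method correctly and resolves
clustered, size-heterogeneous, distractor-laden scenes — not that it will
reach the same scores on arbitrary real slides.

All randomness derives from the single spec seed; identical specs render
byte-identical tiles.

## Problem sizes and numerical choices

End-to-end checks use 512×512 tiles with ~40 nuclei (ten tiles per
condition), chosen to exercise all nine scales and both marker types with a
realistic nucleus density while keeping a full batch comfortably inside a
routine test run; a 1000×1000 tile runs through the full 9-scale × 2-marker
pipeline in roughly one to two minutes on one CPU. Degenerate inputs are
defined rather than special-cased: a constant image is one whole-frame
regional minimum (removed later by the border/size marker exclusions), a
constant FRST map yields no markers, an empty candidate pool yields an
empty segmentation, and a blank white tile returns zero regions.

## Known limitations

* Elliptical standardization discards sub-elliptical contour detail; shape
  features beyond size/orientation would need a contour-refinement stage.
* The rule-based rejection is tuned for ×40, 0.25 µm/px imagery; other
  magnifications require rescaling the scale set (e.g. n ∈ {5..9} at ×20).
* No epithelium/stroma pre-segmentation and no dedicated lymphocyte
  detector: densely packed small distractors at nucleus scale can still
  leak into the result.
* Whole-slide processing (tiling, stitching, sampling) is out of scope; the
  unit of work is a single tile in memory.
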