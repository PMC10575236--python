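# Methods

## Scope and model of the system

The package implements the belt-side processing chain of an automated
fish-landing monitor. The object detector itself (a trained convolutional
network in production) is treated as an exchangeable component behind a
narrow contract: an image goes in, a list of (box, optional polygon mask,
species, confidence) records in original-image coordinates comes out.
Everything else — dataset augmentation, inference preprocessing, detection
postprocessing, morphometrics, evaluation, and session reporting — is
implemented here and validated against a built-in scene generator whose
ground truth is known exactly.

## Coordinate conventions

Pixels are continuous, 0-based, with half-open box extents
[x_min, x_max) × [y_min, y_max), so width = x_max − x_min with no ±1
ambiguity. Polygon labels slightly outside the frame are clipped to the
image rectangle rather than rejected (labeling tools commonly emit
out-of-bounds vertices); a multi-part clip keeps the largest piece.

## Preprocessing

Letterboxing resizes by the single factor s = min(target_w/w, target_h/h)
with bilinear interpolation, pads with constant gray 114 (the conventional
fill; configurable), and splits odd padding remainders bottom/right so the
transform is deterministic and invertible. Normalization divides 8-bit
intensities by 255 after the geometric step (the two operations commute).
The inverse map subtracts padding, divides by s, and clips to source
bounds; a box entirely inside padding cannot be a real detection and is an
error. Round-trip error is below 0.5 px by construction and verified over
randomized sizes.

## Augmentation

Each training image receives exactly one of two background techniques,
chosen Bernoulli(½): (a) background blur — the full image is
Gaussian-blurred (default σ = 8 px) and the labeled pixels composited back
bit-exactly, so no halo is computed from a hole; (b) empty-belt
replacement — all unlabeled pixels are replaced by the same coordinates of
a belt image drawn uniformly from a pool (center-cropped if larger).
Both leave the labeled region bit-identical, which the tests assert as a
sum of absolute differences of exactly zero.

The geometric/photometric menu applies flips (p = ½ each), a rotation
uniform in ±30° about the image center, brightness/contrast changes,
additive Gaussian noise clipped to [0, 255], and optional blur. Polygon
vertices receive exactly the same affine map as the raster
(`scipy.ndimage.rotate(angle)` corresponds to rotating (x, y) coordinates
by −angle about the center; the sign is fixed by a solid-color recovery
test requiring ≥ 95 % pixel agreement). Instances whose clipped area falls
below 4 px² after rotation are dropped as degenerate.

The noise model and the brightness/contrast ranges are configuration-only
with neutral defaults; no values are canonical for them.

## Postprocessing

Pipeline order is size filter → multiclass NMS → rendering.

*Size filter.* Estimated total length (below) is compared against
per-species plausibility rules: discard sardine/anchovy longer than 20 cm
and jack mackerel/mackerel shorter than 20 cm; species without a rule
(jumbo squid, snoek) always pass. The partition preserves input order.

*Multiclass NMS.* Greedy, confidence-descending, class-agnostic: a
detection is accepted iff its box IoU with every already accepted
detection — of any class — is below the threshold (default 0.2). Ties in
confidence are broken by input order (earlier wins). "Very close" is
operationalized as box IoU at or above the threshold; greedy semantics
coincide with pairwise elimination except on overlap chains. The
operation is idempotent, survivor pairs are below threshold, and a
brute-force removal-formulation oracle reproduces it exactly on
randomized inputs. Mask IoU is a possible extension; boxes are used.

*Rendering.* Boxes are stroked in the species' display color with
"species confidence" and optionally "length/weight" text; the input
raster is never mutated and rendering is deterministic.

## Morphometrics

Total length = bounding-box diagonal √(w² + h²) × cm_per_pixel, at native
resolution. The allometric law W = a L^b (W in g, L in cm) is defined for
standard length (snout to hypural crease) but applied to total length,
because a box cannot localize the hypural crease; this biases weights
upward slightly and is accepted as the box-based compromise. Packaged
coefficients: anchovy (0.003653, 3.23344), mackerel (0.0090147, 3.1067),
jack mackerel (0.007921, 3.1085), sardine (0.0064065, 3.1299). Jumbo
squid and snoek have no coefficients and yield length only. Coefficients
vary by season and fishing ground; a different registry file can be
loaded. Fitting uses ordinary least squares on log W = log a + b log L,
the standard fisheries estimator; it requires ≥ 3 positive samples and at
least two distinct lengths.

## Evaluation

Matching is greedy and one-to-one per frame: detections in descending
confidence order claim the highest-IoU unconsumed truth at or above the
matching threshold (default 0.45, a config knob — this is an evaluation
choice, distinct from the NMS threshold), regardless of class, so
cross-class confusions are representable. The confusion matrix is
(N+1)×(N+1) with rows = predicted class + background and columns = true
class + background: unmatched detections are background-column false
positives, unmatched truths are background-row misses, and cell
(background, background) is identically zero. Columns are normalized for
reading; per-class precision is the normalized diagonal and MP is its
unweighted mean. AP uses class-restricted matching and the exact
monotone-envelope (all-point interpolated) area under the
precision–recall curve, checked against an O(n²) step-curve integration
oracle to 1e-9; mAP is the mean over classes.

## Synthetic scenes

Fish are rotated capsules (stadium shapes) with species-specific hue
(±10 % shade jitter) on a gray belt with streak + grain texture. The
capsule polygon, its tight box, and the species are recorded per
instance. Species are drawn from weights proportional to a realistic
plant composition (anchovy 549 : jack mackerel 1339 : mackerel 139 :
sardine 480); the species draw is committed before placement so the
realized mix is exactly multinomial, and rejection sampling retries only
length/position until the pairwise box-IoU cap (`overlap_fraction`,
default 0 = disjoint boxes) is met, erroring after 10,000 attempts.
Lengths are normal with means at typical adult sizes — anchovy 12 cm,
sardine 13 cm (both below the 20 cm filter threshold even after the
diagonal's ~10 % overestimate on rotated bodies), jack mackerel and
mackerel 30 cm, jumbo squid 60 cm, snoek 70 cm — so the size filter is
meaningfully exercised in both directions.

`perturb_detections` corrupts ground truth with independent misses
(miss_rate), Gaussian box jitter, per-ordered-pair species flips
(confusion_rates), truncated-normal confidences, and Poisson(fp_rate)
spurious boxes per frame. Under these known rates the confusion-matrix
diagonal recovers (1 − miss)(1 − Σ flips_out) per class within binomial
3σ bounds, which the acceptance suite asserts at ≥ 1,100 instances.

What the generator does **not** emulate: photorealistic appearance,
lighting and saturation artifacts, fog, deteriorated fish, occlusion
stacks, and visually similar species pairs. Passing tests therefore
demonstrate the correctness of the pipeline's algorithms and accounting,
not detector performance on real belt imagery.

## Reference detector

The reference backend letterboxes to 640×640, estimates the belt tone as
the median content color, thresholds chromatic distance (45 intensity
units), opens with a 2×2 structuring element, labels 4-connected
components (≥ 40 px), assigns each component the nearest palette hue, and
maps boxes back to source coordinates. Confidence is 1 − d/255 for color
distance d. It is deterministic and documented to merge touching
same-hue blobs — a stand-in for exercising the pipeline, not a detector
of real fish.

## Problem sizes and numerical choices

Tests and the acceptance script run scenes at 160×120–400×300 px with
proportionally coarser cm/px calibration (e.g. 0.3 cm/px at 400 px width,
scaled from 0.05 cm/px at full 1920 px frames), keeping fish shapes and
the 20 cm regimes faithful at desk scale. The end-to-end acceptance run
uses 40 scenes (~200 instances) for MP/mAP and ~160 scenes (~1,100
instances) for precision recovery. Weight examples are frozen against a
30-digit arithmetic evaluation; NMS and AP are checked against
independent brute-force oracles; all stochastic tests fix seeds and use
3σ binomial bounds.

## Known limitations

- Box-diagonal length overestimates true total length for rotated or
  partially detected fish; a keypoint-based head/tail model would be the
  next step.
- Box IoU (not mask IoU) drives NMS by default.
- The external-command detector protocol is one PNG per invocation on
  stdin; batch streaming is out of scope.
- Excel/PDF reports are replaced by CSV/JSON with identical content; web
  upload, databases and camera acquisition are out of scope.
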