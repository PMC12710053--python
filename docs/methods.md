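# Methods

## Problem and model

A germination image contains seeds on a near-black, non-reflective
background. Each germinated seed consists of a **seed coat** (the seed
body) and a **radicle** (the embryonic root) growing out of it. The trait
of interest is the radicle's length along its own axis, not the straight
tip-to-base distance.

The pipeline assumes:

* a detector supplies one bounding box and a germinated/non-germinated
  class per seed (boxes typically cover the coat plus only the proximal
  part of the radicle);
* a promptable segmenter produces one binary mask per box or point prompt
  (the `SegmenterContract`); when prompted with a box, its output is
  treated as valid only inside that box;
* coat chromaticity is locally homogeneous and well separated from radicle
  chromaticity in the feature space (R−B, G−B), which is invariant to
  uniform brightness shifts;
* the camera is fixed between the calibration image and the seed images,
  and lens distortion is negligible at the working distance.

## Pixel classification

Coat pixels are modelled as a 2-D Gaussian over (R−B, G−B). The model is
fitted from the 3×3 patch centred on the seed-mask centroid: mean *m* and
(n−1)-denominator covariance *C*. Each pixel is scored with the rescaled
density p = exp(−½ d²), d² the squared Mahalanobis distance, and assigned
to the coat iff p > T (strict — a pixel exactly at T is radicle).

If the features are exactly Normal(m, C), d² ~ χ²₂ and P(p ≤ T) = T: the
threshold *is* the expected fraction of coat pixels lost to the radicle
class. The default T = 0.006 is exposed in config (`classify.threshold`),
and `lenruler sweep` scans the range 0.001–0.010 in steps of 0.001. In the
sweep, Dice/IoU/PA are scored on the radicle class: with fixed seed masks
the threshold only repartitions coat against radicle, so combined-
foreground metrics would be constant in T.

In practice the fit uses only ≤ 9 samples. Two consequences are handled
explicitly:

* **Degenerate patches.** A uniform patch has singular C; whenever
  det(C) < 1e−12 a ridge λ = `ridge_floor`·max(trace C, 1) is added
  (`classify.ridge_floor`, default 1e−6).
* **Estimator variance.** The realised coat false-positive rate for a
  9-sample fit is governed by a Hotelling-T²/F tail, not the χ²₂ tail, and
  typically runs several times T; occasionally a low-variance patch yields
  an over-sharp model with a much higher rate. The pipeline therefore
  applies a morphological opening (3×3) to each stage's radicle mask,
  returning removed pixels to the coat (config `measure.denoise_radicle`,
  default on; skipped if opening would erase the radicle). This preserves
  the coat∪radicle partition and removes the salt-noise specks that would
  otherwise bias the junction selection and the component IoUs.

The fine stage (step 4) re-fits the Gaussian on the 3×3 patch at the coat
centroid obtained from the coarse classification; a single pixel cannot
estimate a covariance, so a patch at that centroid is the minimal workable
training set.

## Skeleton-graph length

Masks are thinned with the Zhang–Suen algorithm (via
`skimage.morphology.skeletonize(method="zhang")`). The skeleton graph has
one vertex per skeleton pixel and 8-neighbour edges weighted 1
(orthogonal) or `skeleton.diagonal_weight` (diagonal). The default weight
is **2** by definition of the metric used here; note this makes the
geodesic a Manhattan-like length that overestimates oblique segments by up
to 41 %, so the geometric alternative √2 — under which the geodesic equals
the Euclidean polyline length — is supported as a config value. Length
accuracy statements below use axis-aligned radicles, where both weights
are exact.

The measurement selects

* **p_e**: the radicle-skeleton endpoint (degree-1 vertex) maximising the
  Euclidean point-to-set distance to the coat skeleton — the tip;
* **p_i**: the intersection point (degree ≥ 3) minimising that distance,
  restricted to p_e's connected component — the junction.

l_p is the Dijkstra shortest-path weight between them. Deterministic
choices for degenerate inputs:

* ties in either selection break by smallest (row, col);
* an unbranched skeleton has no intersection point; the component vertex
  nearest the coat skeleton is used and the seed flagged
  `no_intersection_fallback` (the expected case for clean radicles);
* a multi-component radicle skeleton is measured on the component holding
  the globally farthest endpoint, flagged `skeleton_disconnected`;
* empty radicle mask or skeleton → length 0, flag `no_radicle`;
* a pure-cycle skeleton (no endpoints) treats every vertex as a tip
  candidate.

Non-germinated detections skip classification and measurement entirely
(length 0, `no_radicle`).

## Calibration

The calibration object is a bright quadrilateral of known area S_r on the
dark background (default: 1/64 of an A4 sheet, 210×297/64 = 974.53125 mm²,
configurable). Detection: Otsu binarisation, denoising by erosion+dilation
(opening, disk radius 2), Canny edges, hole filling, largest closed
contour. The four vertices are the contour points nearest the corners of
the contour's minimum-area rotated rectangle (shapely), ordered
counter-clockwise. The pixel area is the cyclic shoelace sum
S_p = ½|Σ(x_i y_{i+1} − y_i x_{i+1})| (implemented for any simple n-gon,
n ≥ 3), the ratio R = √(S_p/S_r) px/mm, and l_r = l_p / R. The 0.5-level
contour sits half a pixel inside the bright region, so S_p underestimates
the rendered square by ≲ 2 % in linear scale at an 80 px side — within the
accuracy the pipeline claims.

## Synthetic scenes

The generator emulates exactly the structure the pipeline relies on:

* elliptical coats (semi-axes 12–22 px) whose pixel chromaticity is drawn
  i.i.d. from Normal(m_true, C_true) with m_true = (85, 35) and
  C_true = [[25, 6], [6, 16]] — a brown coat at blue level 70;
* radicles rendered as width-3 tubes along a centerline of exact polyline
  arc length (default 20–60 px), either axis-aligned straight or gently
  curving; the stored ground-truth length is the centerline length. The
  radicle colour is whitish (features near (5, 5), sd 1), more than 15
  Mahalanobis units from the coat model, so classification difficulty is
  controlled by this single distance;
* ground-truth boxes cover the coat plus the proximal 25 % of the radicle,
  so longer radicles always exit their box — reproducing the truncation
  that motivates the coarse-to-fine design;
* near-black background (12, 12, 14); optional additive luminance noise
  (default 0 — chromatic noise is already carried by C_true);
* with probability 0.1 a seed is placed tangent to an existing one
  (adhesion); placements never occlude an existing seed's pixels, so
  ground truth stays exact;
* an optional bright calibration square of known pixel and mm side.

The default scene is 480×640 with 6 seeds; the test-suite and the
verification script use 240×320 scenes with 3 seeds (and 320×480 when a
calibration square is included) to keep runs fast — the statistical
structure is identical.

The `oracle_backend` wraps a scene's ground truth as a promptable
segmenter: box prompts return the most-overlapping seed's mask (clipped to
the box under `box_clip` corruption), point prompts return the full mask
of the first seed containing a prompt point, and `dilate1` adds one
dilation of boundary error.

What passing tests on these scenes does **not** show: robustness to awns,
shadows, specular bubbles, textured backgrounds, heavily overlapping
radicles, perspective or lens distortion, or the behaviour of any real
detector/segmenter — the oracle backend isolates the measurement pipeline
from segmentation-model error by construction.

## Verification quantities

`scripts/acceptance.py` recomputes, from freshly generated inputs:
geodesic agreement with an independent Bellman–Ford solver (exact, both
diagonal weights); shoelace vs centroid-fan triangulation (≤ 1e−9);
the χ²-tail fraction at T = 0.006 on 10,000 continuous coat-feature draws
(the continuous sampler is used because 8-bit quantisation perturbs the
tail by an amount comparable to the tolerance); the Dice/mIoU identities
(≤ 1e−12); mean absolute pixel-length error over 50 scenes of axis-aligned
radicles (observed ≈ 1.4–1.6 px, a slight negative bias because the
skeleton tip sits ~w/2 inside the tube cap); mean relative mm-length error
over 10 calibration scenes (observed ≈ 2–3.5 %); coarse-to-fine radicle
IoU violations among seeds whose radicle exits its box (observed 0); and
byte-identity of repeated runs. All randomness derives from `--seed`.

## Known limitations

* The degree-based junction definition can mark adjacent skeleton pixels
  as multiple intersection points; the nearest-to-coat rule picks one
  deterministically but the choice can shift l_p by a pixel.
* The weight-2 default metric overestimates curved radicles (up to 41 %
  for diagonal runs); use √2 when physical accuracy on oblique growth
  matters.
* Pixel accuracy (PA) is implemented as intersection-over-ground-truth,
  i.e. foreground recall — the definition used throughout this package —
  which differs from the conventional all-pixel accuracy.
* Per-seed masks may overlap for adhered seeds; no global pixel
  arbitration is attempted (measurements are per seed).
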