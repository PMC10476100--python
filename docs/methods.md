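# Methods

This note documents the models, conventions and numerical choices behind
`berryripe`, and what its synthetic benchmark does and does not show.

## Coordinate and line conventions

Masks are 2-D boolean arrays indexed `[row, column]`; points are `(x, y)`
= (column, row), 0-based, rows increasing downward — so "bottom" (where
the tip of a hanging fruit sits) is maximal `y`. Lines are stored in the
implicit form `A·y + B·x + C = 0`, normalized so `A² + B² = 1`; the
perpendicular point-line distance then reduces to the absolute residual
`|A·y + B·x + C|`.

## Mask preprocessing

An instance mask produced by a detector can be fragmented by occlusion.
`preprocess_mask` keeps the largest 8-connected component (logging a
warning when others are discarded) and fills interior holes. Masks whose
largest component is under 64 px are rejected: quartering a blob a few
pixels across along its longest chord is not meaningful. Contours are
traced with Moore-neighbor tracing (clockwise, west-start), yielding an
ordered, closed, 8-connected pixel boundary; thin shapes are traversed
out and back, so boundary pixels may repeat in the sequence.

## Longest centroid-chord

Every contour point `P_i` defines a line through the centroid `C`. Its
second intersection with the contour is approximated on the opposite side
of `C`: contour points are scored by perpendicular distance to the line,
restricted to negative signed projection onto the direction from `C`
toward `P_i` (without the side constraint, the "other" intersection could
degenerate to a neighbor of `P_i`). On a discrete contour the exact
intersection rarely exists, so every opposite point whose distance
exceeds the minimum by less than 1 px — the discretization scale of the
contour itself — is treated as an admissible intersection, and the
farthest admissible point is taken; the chord is the maximal-length pair
over all `i`, with ties within 1e-6 px broken toward the smallest contour
index for determinism. On convex fruit silhouettes this search agrees
with a brute-force all-pairs scan (segments passing within 1 px of the
centroid) to well under 1 px; strongly concave masks can have
centroid-chords that are genuinely ambiguous, and the method inherits the
nearest-intersection behavior there.

## Partition into R1..R4

Foreground pixels are binned by their signed projection onto the chord
direction at 1/4, 1/2 and 3/4 of the chord length — equivalent to cutting
with the three infinite perpendicular lines, and identical to cutting
with boundary-to-boundary segments for convex contours, while remaining
well defined and O(N) for mildly concave ones. Bins are half-open
`[kL/4, (k+1)L/4)` with the last bin closed, and projections outside
`[0, L]` clamp into the end bins (pixels exactly on a cut line go to the
upper bin; the convention is arbitrary and affects single boundary rows
only). The four bins are then relabeled R1..R4 by descending sub-region
centroid row, so R1 is bottom-most regardless of the chord's direction.
An `EmptyRegion` error is raised if any bin receives no pixels (possible
only for pathological masks). The intersections of each cut line with the
contour are recorded for visualization.

## Color channels and features

HSV and CIELAB (sRGB, D65) are computed with scikit-image and rescaled to
the common 8-bit conventions: S, V → 0-255, H → 0-179 (half-degrees),
L* → 0-255 (L·255/100), a*, b* offset-coded as value + 128. A single
scale across channels keeps one SVM kernel width meaningful for all
features; the default γ = 5·10⁻⁴ is calibrated for these unscaled 8-bit
means, which is why no feature standardization is applied anywhere.

The regional feature vector is the per-channel mean over each sub-region,
channel-major in the fixed order [B, G, L, a, S], region-minor R1..R4 (20
values for the full subset). The two baselines are: method 1, the
bounding-box crop resized to 30×40 with bilinear interpolation and
flattened row-major per channel (background pixels included — it is a
whole-crop method); method 2, the per-channel mean over all foreground
pixels.

## Classifiers

Four families with published defaults: LR (C = 0.7, newton-cg, L2,
multinomial), KNN (k = 12), RF (35 trees, depth 20), SVM (RBF, C = 10,
γ = 5·10⁻⁴). Tuning is stratified 5-fold cross-validation over a grid
(defaults bracket the published optima; user-overridable), selecting the
best mean accuracy with exact ties broken toward the simpler candidate —
grids are scanned simplest-first (fewer neighbors/trees, smaller C).
SVM class probabilities use pairwise-coupled Platt sigmoid calibration
fitted within training (`probability=True`). Evaluation computes the
confusion matrix (rows = true) and one-vs-rest precision, recall and F1
per class, with F1 defined as 0 when P + R = 0. The sub-region ablation
trains one classifier per region (and per region combination) and
tabulates correct test classifications per true stage.

Models persist as a joblib bundle plus a JSON metadata sidecar (feature
schema, hyperparameters, classes, seed, library version); prediction-time
schema mismatches raise rather than silently reorder features.

## Self-calibrated convolution

The block splits a (C, C, w, h) kernel set into four groups K1..K4 of
shape (C/2, C/2, w, h) — the same total parameter count C²wh — and the
input into halves A and B. B is average-pooled by a rate `r` (default 4,
the originating method's published default), convolved with K2, bilinearly
up-sampled (pixel-center alignment, borders clamped), added to B and
passed through a logistic map; the resulting gate in (0, 1) multiplies
the K3 convolution of B, which K4 then convolves; the K1 convolution of A
is concatenated on top. All convolutions are stride-1 cross-correlations
with zero same-padding and no bias; no normalization layers are included.
Inference only — no gradients or training. Correctness is established
against a nested-loop convolution oracle and closed-form special cases
(zero input → gate exactly 0.5; zero kernels → zero output; constant
input with identity-tap kernels → spatially uniform gate logistic(2c)).

## Synthetic data generator

The generator emulates exactly the structure the method exploits:

- **Shape** — a convex teardrop: half-width profile `v^0.5 (1-v)^0.8`
  (v = 0 at the shoulder, 1 at the tip), widest above the midline,
  pointed tip down, elongation (height/width) drawn from 1.25-1.6, ±4%
  size jitter. The silhouette is evaluated analytically per pixel after
  rotating coordinates, so rotation introduces no resampling artifacts.
- **Pose** — rotation within ±30° of tip-down by default (the hanging
  posture the regional ordering assumes).
- **Color** — per stage, the red surface fraction is (0, 0.2, 0.4, 0.6,
  0.8, 1.0); the red/green boundary is perpendicular to the fruit axis
  and placed at the height where the cumulative foreground area from the
  tip equals that fraction, so "one-fifth red" means one fifth of the
  surface, not of the height. Base colors: light green (170, 200, 140),
  ripe red (200, 40, 40), and dark red (140, 20, 30) for Full ripe; a
  smooth transition band of 0.08 fruit heights; Gaussian pixel noise of
  6 8-bit units per channel (the difficulty dial — raising it degrades
  classifier accuracy monotonically); neutral gray background. With
  these defaults the whole-fruit channel-a mean rises strictly across all
  six stages (the darker Full ripe red still has more red area and a
  positive a*) and B/G/L fall, matching the ripening trends the features
  rely on.
- **Scenes** — instances composited on a low-frequency mottled
  background; with a requested occlusion fraction, one pair is placed to
  overlap by that fraction (clipped to 10-50%) and overlapped pixels
  belong to the upper instance, emulating what an instance-segmentation
  stage would hand downstream.

All outputs are pure functions of (parameters, seed): per-instance RNG
streams derive from `SeedSequence([seed, stage, index])`, giving
byte-identical datasets across runs and platforms.

What the generator does *not* emulate: achenes and calyx, specular
highlights, frontlighting/backlighting variation, soft shadows,
non-convex or deformed fruit, and gradual hue transitions within the red
region. Consequently the synthetic benchmark shows that the pipeline
recovers stage structure that is present in the data — not that it
reaches any particular accuracy on field imagery, where transitional
stages overlap and segmentation errors propagate. The benchmark problem
sizes (100 patches per stage for classification, 200 masks for the
geometry oracle, 50 per stage for trend statistics) were chosen as the
smallest at which the measured rates are stable across seeds.

## Known limitations

- The partition assumes a roughly convex mask; severely concave or
  fragmented masks are reduced to their largest component first, which
  can misplace the chord for heavily occluded fruit.
- The six-stage vocabulary is closed: the classifier never abstains, so
  out-of-vocabulary objects (e.g. an unripe fruit type not modeled) are
  forced into the nearest stage.
- Absolute channel values depend on the 8-bit scaling conventions above;
  only trends and classifier behavior, not raw channel numbers, are
  comparable across implementations with different scalings.
- Probabilities come from Platt calibration on small training sets and
  should be read as confidence scores, not calibrated frequencies.
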