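# Methods

This note documents the models, parameter choices and numerical decisions
behind `droi`, in the spirit of a package methods appendix. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs check.

## Coordinate conventions and the camera model

All pixel coordinates are image coordinates: origin top-left, x right,
y down, 0-based, continuous. Normalized gaze uses the same convention;
the `pupil` CSV dialect (origin bottom-left) is flipped with `y → 1 − y`
on read and write. Missing keypoints are the `(0, 0, 0)` sentinel of the
pose-detector JSON dialect and are carried as `present=False`, never as a
position — otherwise a missing keypoint would sit at the image corner and
win spurious nearest-landmark matches.

Visual angles come from a pinhole model with a single intrinsic, the
horizontal field of view: a segment of `d` pixels centered on the axis
subtends `2·atan((d/W)·tan(θ/2))` degrees. The default θ = 90° is a
placeholder; absolute angle values (head widths, dispersion thresholds in
pixels) depend on it, so it must be set to the real optics when absolute
calibration matters. Within the package, angles are used for dispersion
thresholds and size stratification, both of which are tolerance-bounded,
and the synthetic generator uses the *same* camera model to deposit noise,
so recovery results are self-consistent under any FOV.

## Fixation detection

The detector is of the I-DT (dispersion-threshold) family. The dispersion
of a sample window is the **maximum pairwise angular distance** between
its samples — scale-correct on the camera and insensitive to window
length, unlike the classic (Δx + Δy) spread. Defaults: dispersion ceiling
1.5°, duration bounds 80–220 ms, confidence floor 0.6, maximum
inter-sample gap 80 ms. The gap rule exists so a blink cannot bridge two
dwells into one fixation. Vendor tools do not publish their exact
dispersion estimator; the max-pairwise form is documented here as this
package's definition rather than asserted as identical to any tool.

Windows that exceed the duration ceiling are **split** into
`ceil(d / 220 ms)` equal-duration consecutive fixations rather than
truncated or discarded: the attention proportions downstream are computed
over fixation-frames, so discarding long dwells would bias attention away
from whatever holds gaze longest. With the default bounds every split
chunk is at least 110 ms ≥ 80 ms; for custom parameter sets where a tail
chunk falls under the minimum it is dropped. The window dispersion bounds
each chunk's dispersion, so every emitted record satisfies both bounds
(asserted per record in the tests).

Incremental bookkeeping keeps the detector O(n·w) for window length w
(each new sample only measures distances to the current window).

## Registration

A fixation spanning k frames contributes k fixation-frame assignments; all
statistics are over fixation-frames. Confidence filtering is strict
(`> 0.6`), applied per landmark (whether the original confidence cut was
per landmark or per person is not knowable from outside; per-landmark is
the finer-grained choice and is config-switchable by filtering before or
after). Nearest-landmark search is exhaustive over all persons' present
landmarks with deterministic tie-breaking: distance, then person index,
then body before face, then landmark index.

ROI maps ship as documented defaults because no published index→category
mapping exists for this task. Body model: head = {nose, neck, eyes, ears}
(indices 0, 1, 15–18), everything else body. Face model (standard 68+2
layout): jaw and brows (0–26) = face exterior, 27–35 = nose, 36–41 + 68 =
image-left eye, 42–47 + 69 = image-right eye, 48–67 = mouth. "Left/right"
are viewer-perspective. Both maps are constructor arguments.

Face visibility (full vs partial) uses raw landmark presence — all 70
present ⇒ full — deliberately before confidence filtering, since a
confidently-detected but averted face should count as partial through its
missing landmarks, not through low confidence. Head width is the
ear-to-ear landmark distance (body ears 17/18, or the jaw-contour
endpoints 0/16 for face detections) converted to degrees; a missing ear
makes the face unmeasurable rather than guessing.

## Attention statistics

Two denominators are reported, because they answer different questions:
`all_fixation_frames` (how much of total attention went to people) and
`detected_frames` (attention conditional on a person being detectably
present). A frame counts as "detected" when at least one person detection
survives confidence filtering — the frame-level reading; per-fixation
gating would be stricter and can be emulated by filtering assignments.
Facial-region registrations count as head fixations in the summaries.

Size stratification associates each fixation-frame with the ear-to-ear
width of the nearest measurable face in that frame and splits at the mean
width, strictly above vs at-or-below (with a 1e-9 relative tolerance so
identical widths cannot land above their own mean through float
summation). The linkage rule — nearest measurable face — is this
package's choice; no standard exists.

Split-half reliability is the Spearman correlation between segment-wise
proportions, with the confidence interval from the Fisher z transform
using the rank-correlation variance `1.06/(n − 3)`. The partial Spearman
correlation uses the first-order partial-correlation identity on the three
pairwise Spearman coefficients, which equals correlating the residuals of
rank regressions; the degenerate case covariate ≡ y (0/0) is defined as 0.

## Face template, projection, heatmaps

The canonical 70-point template is a synthetic, bilaterally symmetric
frontal face built from parametric curves in a nominal 200×200 box
(jaw half-ellipse, brow arcs, nose axis and nostril line, six-point eye
rings with center pupils, two lip ellipses). It is config-replaceable; its
exact geometry only defines the common coordinate system, not any measured
quantity.

The Delaunay triangulation is computed **once on the template** and
transferred to each frame's detected landmarks by vertex correspondence.
Re-triangulating per frame would occasionally flip diagonals and break the
triangle correspondence that the per-triangle affine map requires.
Triangles are ordered deterministically (sorted vertex triplets,
lexicographic order), so point-in-triangle lookups resolve shared edges
identically on every run. Barycentric coordinates are solved per triangle
with a 2×2 inverse; a point is inside at weight ≥ −1e-9, and weights are
clipped and renormalized on return. Because affine maps preserve
barycentric coordinates, projection is exact (to float precision) under
any affine distortion of the face — the property the acceptance checks
measure at ~1e-13 template units over 1,000 random distortions.

Heatmaps deposit an isotropic Gaussian per projected fixation, evaluated
at cell centers of a 64×64 grid over the template bounding box, and
normalize to total mass 1. The default bandwidth is 2% of template width —
small enough to keep the eye/nose/mouth structure separate, large enough
to smooth single fixations; it is a display/aggregation parameter with no
downstream inferential role, and is config-overridable. Fixations outside
the detected-face hull are excluded from heatmaps but still count in the
region proportions if within the 30 px landmark threshold — the two
measures are defined independently. Heatmap PCA centers the flattened
grids across participants and uses a full SVD; an all-identical input
yields zero components rather than NaN ratios.

## Face diets

Identity clustering runs K-means for k = 1..k_max (default 8, 5 seeded
restarts) and picks the elbow of the WCSS curve: both axes normalized to
[0, 1], maximum perpendicular distance to the chord between the curve's
endpoints. A guard handles the no-structure case: if no single step shrinks
the WCSS by at least 10% (relative), the curve has no elbow and k = 1 is
returned. The guard's margin is wide in both directions on the synthetic
embeddings: splitting an unclustered Gaussian cloud shaves ≤ ~5% per step,
while reaching a true cluster count removes ≥ ~12% in one step (measured
in the acceptance runs, which recover planted k ∈ 2..6 in 50/50 seeded
runs at 10σ separation).

The morph average is two-level by construction: crops are piecewise-affine
warped to the template, averaged within identity, identity means are
averaged with equal weight, and the grand mean is warped to the
equally-weighted mean landmark geometry. This makes the result invariant
to per-identity crop multiplicity — the "equal contribution per identity"
rule — which the tests verify as 0.4 ± 1/255 for constant crops of 0.2
and 0.6 with a 4:1 crop-count imbalance. Warping is inverse-mapped per
destination triangle through shared barycentric weights, with bilinear
sampling and mid-grey fill outside the hull; an independent
piecewise-affine implementation (scikit-image) agrees within interpolation
tolerance in the tests.

Embedding computation is out of scope: embeddings are consumed from CSV,
and the generator produces labeled surrogate embeddings (unit-variance
Gaussian blobs with centroids `separation` σ apart along orthogonal
directions), which exercise the clustering logic without trained weights.

## The synthetic generator

The generator emulates the *measurement situation*, not its appearance:
a 1920×1080, 60 fps scene camera; a 120 Hz gaze stream; pedestrians as
scaled canonical 25-point stick figures (300–700 px tall, ≤ 1.2 px/frame
linear motion with boundary reflection) with 70-point faces attached above
400 px of height; planted fixations drawn from a gaze policy whose
defaults (head 4.3%, body 11.6%, background 84.1%) match attention rates
observed for adults navigating busy public spaces; dwell durations
100–200 ms; 40 ms saccades; deposit noise 0.1° of visual angle (well
inside the ~0.6° accuracy of wearable trackers), applied in angular units
and converted through the camera model. Landmark confidences are uniform
on [0.7, 1], with 3% of keypoints dropped to sub-threshold confidence and
20% of faces losing a random landmark subset (occlusion). The interaction
scene is one full-landmark frontal face subtending 8.2° ear-to-ear with
1 px frame jitter, and a five-region target distribution.

Ground truth records every planted fixation's label, target person and
landmark, onset and duration, so parameter recovery is testable: on
noise-free scenes the pipeline recovers 100% of planted labels, and at the
default noise the acceptance run recovers ≥ 95% of planted dwells with
< 0.3° centroid error.

What the generator does **not** emulate — and what passing tests therefore
do not show about real recordings: pose-detector failure modes correlated
with appearance (phantom bodies, left/right swaps), rolling-shutter and
motion blur, gaze-camera parallax, smooth pursuit of walking people beyond
slow target motion, person tracking across frames, and any photometric
realism in the face crops. The pipeline's statistical machinery is
validated; detector-facing robustness must come from the real detector's
own validation.

## Known limitations

- The pixel↔degree conversion depends on an FOV the user must supply;
  shipped defaults are only internally consistent.
- Navigation-mode synthetic scenes keep all persons in view, so the two
  attention denominators coincide there; the distinction is exercised with
  hand-built frames in the unit tests.
- The elbow rule's 10% improvement guard is calibrated for well-separated
  embeddings; heavily overlapping identities (separation ≲ 3σ) will be
  under-segmented.
- Registration is frame-wise; no person re-identification links
  assignments of the same pedestrian across frames in navigation mode.
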