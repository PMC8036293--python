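# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `kerato3d`. It is the design record a maintainer should
read before changing defaults.

## Problem and pipeline

Keratoconus deforms the cornea from a near-spherical cap into a cone. The
package grades that deformation from two ordinary photographs — one frontal,
one lateral — by reconstructing the corneal geometry and measuring how
steeply the corneal surface rises from the limbus plane (the plane of the
iris rim). The stages are graded from the steepness angle `s` of the
greatest corneal slope:

| steepness `s`     | stage                              |
|-------------------|------------------------------------|
| no cone detected  | normal                             |
| `s < 45°`         | mild                               |
| `45° ≤ s ≤ 52°`   | moderate (also called "advanced")  |
| `s > 52°`         | severe                             |

Both boundary values grade *moderate* (the inclusive reading of the
published band). "Moderate" and "advanced" are the same class; one label is
used throughout.

The per-case chain is: iris detection → cross-view keypoints → lateral depth
landmarks → view fusion (optionally a rasterized 3D volume) → curvature
triangle + steepness → stage. A 3D CNN classifying reconstructed volumes is
an independent second branch; by default both run unchained (a config flag
`cnn_gates_staging` makes the CNN gate the geometric staging instead, for
the control flow in which staging only refines a positive detection).

## Synthetic eye phantoms

No clinical images ship with the package; every claim is tested on
parametric phantoms with analytically known geometry.

* **Frontal view** — anti-aliased dark iris disc (radius `R`, with a darker
  pupil at 0.45 R) on a light sclera. The strongest circular edge is the
  limbus at radius `R`.
* **Lateral view** — a profile silhouette. The corneal contour over the
  limbus chord is a *spherical cap* for normal corneas (circle radius
  `R / sin s`, apex height `R · tan(s/2)`; maximal slope `s` occurs where
  the arc meets the chord) and a pair of *straight conical flanks* for
  keratoconus (apex height `R · tan s`; slope `s` everywhere on the flank).
  Straight flanks were chosen over a blended/truncated cone because they
  make the ground-truth maximum slope exactly `s`, which is the quantity
  every downstream test recovers. The silhouette edge uses a 2-px intensity
  ramp: with a 1-px ramp, near-45° flanks produce marching-squares staircase
  wobble that biased measured steepness by ≈ +1.4°.
* **Volume** — the corneal elevation surface rasterized as a thin voxel
  shell; grey level encodes elevation (dark = high, light = flat), matching
  the input convention of the CNN branch.

Default stage steepness ranges are normal 30–40°, mild 41–44°, moderate
46–51°, severe 53–65°, leaving 1–2° guard bands around the 45°/52°
boundaries so no phantom's label is ambiguous. The generator refuses ranges
that straddle a boundary. Default noise is additive Gaussian with σ = 2
intensity units on the 0–255 scale (≈ 1 % of full range, a modest
sensor-noise level); intensity noise only — no specular highlights, no
eyelid occlusion, no texture. Cohorts are fully determined by one seed.

What phantom-based tests do **not** show: robustness to real-eye texture,
eyelash/eyelid occlusion, off-axis gaze, uncontrolled lighting, or camera
calibration. The phantoms validate the geometry and the code, not clinical
performance.

## Iris detection (circular Hough transform)

A circle `(x−m)² + (y−n)² = r²` is sought on a Canny edge map
(Gaussian-gradient magnitude, non-maximum suppression, hysteresis; σ = 2).
The vote definition is exact and shared by two independent implementations:
an edge pixel votes for `(m, n, r)` iff its rounded distance to the center
equals `r`. The fast path computes each radius plane of the accumulator by
FFT convolution of the edge map with the ring's indicator kernel and rounds
to integer counts; `bruteforce_accumulator` recounts by direct enumeration
and serves as the test oracle. Votes are normalized by ring size (supported
fraction of the circumference, in [0, 1]); candidates whose circle leaves
the frame are excluded; a best fraction under `min_support` (default 0.25)
raises `NoCircleFound`.

Tie-break: smallest radius, then lexicographic (row, col). Consequence: a
radius range that includes both the pupil and the limbus returns the pupil
when both circles are complete, so the searched radius range is a real
parameter — the pipeline's default `(size/10, size/4)` excludes the phantom
pupil; for arbitrary images the range must be supplied.

## Depth from the lateral view

The Otsu-thresholded silhouette boundary is traced at subpixel resolution by
marching squares; the *rightmost profile* (largest boundary column crossing
each row) is the corneal contour function. The apex `p1` is the profile
maximum (center of the maximal plateau, so a flat profile yields its middle
row); the chord endpoints `p2`, `p3` sit one iris radius above and below the
apex row. The corneal depth is the leg of the right triangle with hypotenuse
`p1−p2` and base the projection of `p1−p2` on the chord:

    d² = |p1 − p2|² − ((p1 − p2) · û)²,   û = (p3 − p2)/|p3 − p2|

which equals the perpendicular distance from the apex to the chord line (the
oracle used in tests) and reduces to the half-chord form when the apex sits
over the chord midpoint. Whether the published construction meant
apex-to-chord or apex-to-endpoint distance is ambiguous; apex-to-chord is
implemented (it is the one consistent with the triangle figure), and the
worked examples pin it.

## Steepness measurement

Steepness is measured on the subpixel profile between `p2` and `p3`,
resampled at ¼-px steps (`atan |d col / d row|`; pixels are isotropic so the
"cornea-enclosing rectangle" normalization is the identity here). Two
estimators are combined:

* interior: Savitzky–Golay local quadratic fits over a 5-px window
  (`deriv=1`) — unbiased on straight cone flanks, robust to contour-tracing
  wobble;
* endpoints: a spherical cap attains its maximum slope exactly at the chord
  junction, where any interior window under-reads. One-sided secant slopes
  over windows `w` and `w/2` (w = 4 px) are Richardson-extrapolated to zero
  window (`2·s(w/2) − s(w)`), recovering the junction tangent.

The test suite bounds the noise-free recovery error at 1° across 30–65°
phantoms (the observed errors are far smaller), and end-to-end staging
remains exact on guard-banded cohorts at the default noise level. The
hemisphere limit (edge tangent → 90°) is approached but never reached at
finite sampling.

**Cone detection.** A case is keratoconic when the corneal depth exceeds
0.60 × iris radius. Under the phantom geometry, normal caps have
`d/R = tan(s/2) ≤ tan 20° ≈ 0.36` and the shallowest cone has
`d/R = tan 41° ≈ 0.87`, so 0.60 sits in the geometric gap between the two
families. (A much smaller threshold would flag every normal cap as a cone.)
The threshold is exposed in `PipelineConfig.cone_depth_ratio`.

## Apex angle (law of cosines)

From the displacements already available — `d1 = |p2−p3|` (chord),
`d2 = |p1−p2|`, `d3 = |p1−p3|` (apex to chord endpoints) — the apex opening
angle is `θ = arccos((d2² + d3² − d1²)/(2 d2 d3))` and the *angle of
curvature* is `180° − θ` (flat cornea → small, sharp cone → large). For a
symmetric cone of steepness `s` this angle equals `2s` exactly, which is the
ground truth used in the agreement experiments. The staged quantity is the
tangent-slope steepness; θ and 180°−θ are reported alongside, since all
three vocabularies appear in practice.

## Orthogonal-view fusion

The global frame is anchored to the frontal image: x = frontal column,
y = row (shared vertical axis), z = depth (lateral column). A single
homogeneous translation `T = (tx, ty, tz)` places the lateral image plane in
that frame; it is estimated in closed form as the component-wise mean of the
lifted-correspondence residuals, which recovers a consistent translation
exactly from a single pair. The published transform is translation-only;
rotation/scale between views is handled by canonicalizing image orientation
at load time, not by `T`. In the pipeline the correspondences are the limbus
landmarks seen in both views (top/bottom limbus and center), which anchors
`tz` so the limbus chord plane maps to z = 0 and the fused apex z equals the
corneal depth. Keypoint matches can be used instead (`use_sift_transform`),
with a landmark fallback (flagged) when fewer than `min_matches` survive the
ratio test — texture-poor phantoms always fall back; the keypoint branch
exists for textured inputs.

The volume is built by revolving the lateral depth profile around the
corneal axis across the frontal iris disc (rotational symmetry is the
modeling assumption; real keratoconus cones are often decentered — a stated
limitation), interpolating the surface with a thin-plate spline, depositing
a unit-intensity shell and Gaussian-smoothing (σ = 1 voxel). Volume-to-volume
match scores are plain sums of squared intensity differences, with trilinear
resampling when grids differ.

## Keypoints

Scale-space keypoint detection and description (difference-of-Gaussian
extrema; 4×4×8 = 128-dimensional gradient-histogram descriptors,
L2-normalized) is delegated to `skimage.feature.SIFT` with the canonical
parameters (4 octaves, 3 scales/octave, σ₀ = 1.6, contrast cut 0.013).
Matching is the nearest-neighbor ratio test at 0.8 (each source keypoint in
at most one pair); a single-candidate set falls back to an absolute distance
cap of 0.5 on unit-norm descriptors. Invariance figures measured on a
seeded blob-texture fixture: ≥ 80 % position correspondence under 90°
rotation and ≥ 60 % under half-scale, counting deduplicated positions
(multi-orientation keypoints at one location collapse to one position)
matched greedily one-to-one within 2 px.

## 3D CNN

Architecture: four blocks of (3×3×3 valid convolution → ReLU → 2×2×2 max
pool) with 96/128/256/512 kernels, two fully connected layers of width 1000,
softmax over (normal, mild, moderate, severe); plain SGD on cross-entropy,
batch 32, learning rate 0.01, up to 30 epochs. The published input edge of
227 voxels with these kernel counts is beyond desk-scale memory, and the
published per-layer output sizes are not internally consistent under any
standard stride/padding, so the *topology* is reproduced and the input edge
is configurable (default 64, the smallest power of two that survives four
conv/pool halvings with room to spare; 46 is the arithmetic minimum). The
engine is written in NumPy: convolutions as single im2col GEMMs (column
matrices cached for the backward pass; the input-gradient GEMM uses an
explicitly contiguous transpose), pairwise-maximum pooling whose backward
routes gradients to block maxima (a deterministic subgradient; ties occur
essentially only in all-zero post-ReLU blocks, where the ReLU mask blocks
them anyway), and gradient accumulation in fixed-size sample chunks so peak
memory stays bounded while batch gradients are exact. glibc's malloc mmap
threshold is raised at import so the large activation buffers recycle
through the heap instead of round-tripping through page-zeroed mmaps.

**Conditioning for fixed-rate SGD.** The training budget is a few dozen
parameter updates (40 samples, batch 32, ≤ 30 epochs), so the optimization
must be well-scaled from the first step; a fixed learning rate leaves no
schedule to hide behind. Three measures, all initialization-side and all
documented as this package's design:

1. inputs are standardized on training-set mean/std (constants stored in the
   model and applied at inference);
2. variance-calibrated (LSUV-style) initialization: each conv/hidden layer
   is rescaled on a class-spanning probe batch so its output std is 1; the
   last hidden layer is rescaled so the **between-sample** std of the
   feature vector is 0.4 — the feature components shared by all samples
   cancel in the softmax for class-balanced batches, so it is the
   between-sample (discriminative) variance that sets the effective step
   size, roughly `lr · |p−y| · ‖h_centered‖²` per logit per step;
3. the softmax layer starts at zero, so initial logits vanish and the first
   loss is exactly `ln 4`.

Training history records the running per-epoch loss/accuracy. Fixed-rate
SGD oscillates once the set is nearly memorized, so training keeps a
checkpoint of the best epoch (highest accuracy, ties broken by lower loss),
restores it at the end, and stops early on full memorization or when the
best has not improved for 5 epochs. Because an epoch's running metrics
describe (up to intra-epoch drift) the parameters the epoch *started* from,
the checkpoint stores the pre-epoch parameters — storing post-epoch
parameters under the running metric mislabels them by one update and can
hand back a model far worse than its recorded accuracy. Without calibration (flag off) the same
code trains, just far more slowly at this step budget.

Preprocessing to the network's input space: supra-threshold (5 % of max)
bounding-box crop padded 10 %, *isotropic* trilinear resample into the input
cube with centered zero padding — an anisotropic fit would normalize away
the cornea's height-to-width ratio, which is precisely the severity signal —
then a 3D Gaussian filter (σ = 1 voxel) and min–max scaling to [0, 1];
constant volumes pass through unchanged.

## Evaluation statistics

Two metric conventions coexist deliberately. The literal forms —
`sensitivity = TP/(TP+FP)`, `specificity = TN/(TN+FN)`,
`accuracy = (TP+TN)/(TP+FP+FN+TN)` — are the ones the reproduced study
prints (its 98.45 % = 254/258 and 96.00 % = 96/100 only follow from these);
the textbook forms are exposed under distinct names (`recall`,
`specificity_tn_fp`). Likewise the 4-class confusion matrix reports both a
strict-diagonal TP and a "row total minus misses into the normal column"
reading, because the reproduced table mixes the two (its moderate-row TP is
the row total, its mild-row TP the diagonal); reports say which is used, and
the package's own default multi-class accuracy is strict-diagonal.

k-fold cross-validation is stratified (per-class fold sizes differ by at
most one; every case tested exactly once), seeded, with fold-averaged
accuracy/precision/recall/F1. Pearson correlation uses the sample form
(n−1 normalization, sample SDs). Bland–Altman agreement reports the mean
difference, its SD and the mean ± 1.96 SD limits, plus a per-pair
(mean, difference) table for plotting.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run at 1 000 random instances (depth, apex angle) and 20
seeded ≤ 128² phantoms (Hough equivalence). End-to-end staging and CNN
training use a 40-case noise-free cohort (10 per stage) at 256² images and
72³ volumes, preprocessed to 64³ — sizes chosen so the full suite runs on a
single CPU in minutes while every stage still operates far from degenerate
limits. The CNN's published configuration trains the same code path at
larger `input_edge`.

## Known limitations

* Rotational symmetry of the reconstructed cornea; decentered cones are
  averaged toward the axis.
* Translation-only view alignment; view-angle-robust fusion is out of scope
  (volume rotation is provided as a post-hoc utility only).
* The geometric cone detector is a depth-ratio rule, not a shape test; very
  shallow cones (steepness well below 41°) would be called normal.
* No physical calibration: all lengths are in pixels with unit aspect; no
  keratometry in diopters, no pachymetry.
* Phantom realism is geometric, not photometric; clinical accuracy claims
  cannot be made from these tests.
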