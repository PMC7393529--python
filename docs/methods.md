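# Methods

This note documents the models, parameter choices and numerical
decisions behind `facekin`, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Scope and assumptions

The pipeline assumes one frontal, upright face per frame against a
plain background, recorded together with mono audio of isolated word
utterances. It measures **vertical** articulatory motion only — head
(via the nose tip), left eyebrow, and lip aperture — relative to each
token's first frame, and corrects for **translational** head movement
only. Head rotation and tilt are out of scope; if present they should
be removed beforehand by registering frames to a reference.

## Audio token segmentation

Short-time energy (STE) is the windowed sum of squared samples; the
window is 400 samples (25 ms at 16 kHz, a standard speech analysis
window; the reference parameterization fixes the step at 1 sample but
not the window length) and the energy is median-filtered with order 5.
The utterance threshold is 20% of the maximum of the *filtered energy*.
The description of the threshold is ambiguous between raw amplitude and
energy; energy was chosen because the median filter sits between the
STE and the clustering steps in the reference parameter listing, and a
squared-signal threshold is more robust to single-sample clicks. A
cluster is a maximal contiguous supra-threshold run; runs shorter than
35% of the longest are discarded as noise. Cluster endpoints are
energy-window start indices; they map to video frames by
`floor(sample / rate · fps)`, and each segment is padded by 10 frames
on both sides, clipped to the video, with buffer-induced overlaps
merged so no frame lands in two token files.

Degenerate-input guard: when more than 90% of the energy samples are
supra-threshold, the recording has no token structure that a relative
threshold can separate (e.g. a bare noise floor, where the maximum *is*
the noise), and segmentation returns no tokens rather than one
recording-length token.

## Region detection

The coarse ROI stage is defined as a *pluggable box detector* swept
over a merge-threshold schedule: start low (many raw detections) and
raise the threshold until exactly one box remains (face and nose: 1–150
step 10; eye pair: 0–150 with the step halved, floor 1, whenever the
detection count fails to decrease; left eye and mouth: 4–150 step 10).
The reference implementation uses pretrained cascade classifiers behind
this loop; cascade model files are an optional runtime plug-in, while
the bundled `GeometryDetector` locates the same regions from HSV color
bands and connected components, with `merge_threshold` acting as a
minimum component area (in resolution-scaled units) so that higher
thresholds monotonically prune detections. This keeps the adaptive
loop, and everything downstream of it, fully testable on rendered
fixtures; the geometry detector's color rules are tuned to the bundled
renderer's palette and are not expected to work on photographs.

Part refiners:

* **Nose**: an edge-based (geodesic) active contour, initialized from
  the nose box, ≤500 iterations, smoothing 2, negative balloon; the
  speed image is `inverse_gaussian_gradient(gray, alpha=1000, sigma=1)`
  with stopping threshold 0.5 — the sharpening (high alpha, small
  sigma) is needed because the nose occupies only a few pixel rows at
  low resolutions and softer gradients let the contour collapse. The
  keypoint is the coordinate-wise mean of the lower-edge contour (the
  bottom-most mask pixel per column).
* **Eyebrow**: the search region is the left-eye box plus the band of
  the same height above it. Three evidence maps are fused additively
  after max-normalization, with equal weights: (1) patch contrast — a
  P×P block ending just above a pixel minus the block starting at it,
  P = 10% of the eye-box height (floored, minimum 1), positive where
  bright skin sits above the dark brow; (2) Canny edges of the HSV
  value channel, restricted to the top half of the region; (3) the
  boundary of a Chan–Vese region contour (≤400 iterations) initialized
  from the eye box shifted up by 60% of its height (the reference
  method estimates the eyebrow box "from the position of the eye"
  without numbers; 60% places the initializer over the brow for
  ordinary face proportions). The ridge is the arg-max row of the
  per-row totals, ties to the upper row. Row totals are pooled across
  adjacent rows (1-px Gaussian) first: Canny marks one side of an edge
  and a contour boundary the other, so the same physical edge splits
  its evidence across neighboring pixel rows, and without pooling a
  weaker but pixel-aligned row (the brow's bottom edge) can win.
* **Lips**: inside the mouth box (expanded by 15% so the box border
  does not clip the lip boundary), the H and S channels are binarized
  by Otsu's method (the binarization thresholds are unspecified in the
  reference; Otsu is parameter-free). If both channels turn ON more
  than 48% of pixels the masks are intersected, otherwise the dominant
  channel's mask is used. Largest component → convex hull → dilation
  by a radius-7 disk → edge-based active-contour refinement (≤500
  iterations, smoothness 2). The outline is split at the extreme
  occupied columns (oral commissures); the upper/lower keypoints are
  the outline points at the column midway between the commissures (the
  precise geometric definition of the Cupid's-bow point is not given;
  the midpoint-column convention is used).

Coordinates are 0-based pixels, origin top-left, x rightward, y
downward; boxes cover `x..x+w-1`, `y..y+h-1` inclusive.

## Tracking and compensation

The tracker is pyramidal Lucas–Kanade (KLT), implemented in-package
(no installed library provides sparse point tracking): 3 pyramid
levels, 31×31 integration window, ≤30 Gauss–Newton iterations per
level with 0.01-px convergence, Gaussian presmoothing (σ = 1) per
level, bilinear subpixel sampling, template gradients by central
differences. These settings are the package's own defaults (the
reference leaves them to its vision library) and are recorded in
`TrackerConfig`. A point that leaves the image is re-filled by
extrapolating its last valid displacement and flagged `lost`; the
reference does not discuss tracking loss, so this fail-soft policy is
the package's own.

Head compensation subtracts the nose displacement from every other
track: `p(t) ← p(t) − (nose(t) − nose(0))`. It is exact for global
translations; applying it twice is an error, not a no-op.

Landmark accuracy is scored as the minimum Euclidean distance from an
automatic point to a reference curve, divided by the **frame height**
and expressed in percent. The reference protocol normalizes "by the
image resolution (1080 × 1920)" without fixing the dimension; height is
used because vertical motion is the measured axis, and the choice is
recorded in output metadata.

## Features

All 33 features derive from the per-ROI displacement profile
d(t) = y(0) − y(t) (head, eyebrow; raising positive because image y
grows downward) or d(t) = g(t) − g(0) with aperture
g = y_lower − y_upper (lips; opening positive). Velocity and
acceleration are first and second finite differences scaled by fps and
fps² — reported per second, while the underlying per-frame differences
are what the reference computes. Per ROI: max positive d, max |negative
d|, mean |d| ("average distance"), path length Σ|Δd| ("total
distance"); the statistics named but not defined in the reference are
pinned down as written here. Relative times are extremum index divided
by T−1 so they span [0, 1]; a profile with no positive (or negative)
excursion contributes 0 for that magnitude and its relative time; ties
resolve to the earliest frame. Distance *and* kinematic features are
divided by the head size (the reference's normalized velocity and
acceleration plots show kinematics in normalized units); time features
are dimensionless. Conversion to millimetres multiplies by the
physical head size and relabels units.

Horizontal displacement never enters any feature.

## Forest-based feature significance

One-vs-all reduction per class; balanced bootstrap (r rows per class,
with replacement) repeated N times; per repeat a stratified 90/10
train/test split (stratification is the package's choice; the
reference states only the 90/10 ratio), a random forest (t trees,
minimum leaf 20, √p features per split — the standard default; the
reference is silent on the split count) fitted on the training part
with OOB bookkeeping. Defaults r = 500, N = 300, t = 500 follow the
reference's stated values (its parameter table also shows "repeat
sampling 100 times"; the text's N = 300 is used).

Significance mechanics, where the reference is under-specified, are
resolved as follows and implemented in-package on top of scikit-learn's
forest fit: a feature column is permuted across all rows (each row is
OOB for ~37% of trees, so forest-level OOB covers essentially every
row), OOB majority votes are recomputed — only trees that split on the
feature need re-prediction — and the correct/incorrect counts are
pooled over 50 permutation repeats into one 2×2 table per feature per
bootstrap repeat (pooling stabilizes small-count tables). Pearson's χ²
of independence, without Yates continuity correction (the reference
names the plain Pearson test), gives the p-value; for a 2×2 table the
closed form n(ad−bc)²/(r₁r₂c₁c₂) is used and is verified against
`scipy.stats.chi2_contingency(correction=False)` in the test suite. A
feature the forest never split on leaves the votes unchanged and gets
p = 1. Per-feature p-values are pooled across the N bootstrap repeats
by their **median** (robust to outlier repeats), then
Benjamini–Hochberg adjusted across features (via statsmodels); adjusted
p < α = 0.05 flags significance. Permutation importance (mean OOB
accuracy drop) is estimated from the same permutation stream — the
reference uses 50 iterations for both purposes. OOB vote ties and
never-OOB rows resolve to the negative class / are excluded from the
counts. The reference's parameter listing shows an undefined "trainX
interaction" term in the forest call; no interaction features are
constructed.

All randomness flows from one master seed through `SeedSequence.spawn`
(per class, per bootstrap repeat), making every result bit-reproducible
given (seed, config).

## Synthetic fixtures

The renderer draws an anti-aliased schematic face — skin ellipse,
darker-shaded nose (lower half-ellipse), eyebrow bars, sclera/pupil
disks, crimson outer-lip ellipse with a dark interior that opens with
the aperture waveform — plus a faint (±3%) luminance texture that
translates with the head so gradient-based tracking is well-conditioned
everywhere. Ground truth (keypoint tracks, contours sampled at ~0.5 px,
lip mask, eye centers) comes from the same analytic layout. The
scripted default motion emulates one monosyllabic utterance: head sway
~1.1% of frame height, one eyebrow raise ~2.3%, one lip open–close
cycle ~3.7% — at 1080p about 12, 25 and 40 px, the order of magnitude
of real articulatory excursions. The renderer reproduces the
color/intensity structure the refinement stages consume (HSV lip
contrast, dark-brow contrast, intensity edges) but **not** photographic
appearance: passing on renders validates the geometry, fusion,
contour, tracking and statistics machinery, not the appearance-based
cascade detectors, which sit behind the pluggable interface.

One renderer-specific subtlety: the ground-truth nose keypoint is the
*mean* of the lower-edge arc, which sits (1 − π/4)·depth above the arc
itself, so even a perfect detector scores a small nonzero
distance-to-curve error on the nose (~0.27% at 1080p with the default
layout). Audio fixtures are bursts of band-limited (4th-order
Butterworth-filtered) noise normalized to an exact peak over a known
noise floor, with exact sample intervals as ground truth. Trajectory
fixtures return analytic tracks together with feature values computed
by an elementary plain-loop reference that shares no code with the
extractor; it differences the raw displacement and normalizes
afterwards — mathematically identical to the extractor's definition,
and extremum ties on analytically flat segments (a triangle ramp's
constant velocity) then resolve on the same float sequence instead of
flipping on last-ulp rounding noise.

## Problem sizes used in validation

The synthetic-analog accuracy check uses five 1080×1920 videos — 128
frames in the acceptance script, 48 in the test suite — probed at the
reference protocol's frames 4, 8, 16, 64, 128 (clipped to the token
length). The repeated statistical suites run at desk scale: the type-I
suite uses 500 two-class null tables of 60 rows per class with N scaled
from 300 to 20, 12 trees, r = 40, 5 permutation repeats; the power
suite uses 20 four-class tables of 500 rows per class with 60 trees,
r = 150, N = 5, 20 permutation repeats. Forest behavior at these sizes
is the same mechanism at smaller counts; absolute importances shrink
with tree count but the rank order and the χ² calibration, which are
what the checks assert, do not depend on the full-scale configuration.

## Known limitations

* Translational compensation only; rotation/tilt require external
  registration before the pipeline.
* One face per frame; no profile or strongly tilted faces.
* The bundled geometry detector is fixture-oriented; real video needs a
  cascade (or equivalent) detector plugged into the same interface, and
  the HSV lip rules assume lips redder than skin.
* Lip keypoints are tracked reliably only when the mouth is large
  relative to the 31-px tracking window (roughly ≥540-px frame height
  for the default layout); at very small scales opposite lip edges fall
  inside one window and their motions cancel.
* The left eyebrow only, matching the reference method.
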