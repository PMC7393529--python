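# facekin

Automatic detection, tracking and statistical analysis of **facial
articulatory movements** in speech videos.

Speech production is visible: the head nods, the eyebrows rise, the lips
open. Quantifying these cues has traditionally required either human
annotators (subjective, non-quantitative) or gluing sensors to the
speaker's face (precise but invasive, and limited to the sensor sites).
`facekin` measures them directly from ordinary video of a single frontal
speaker against a plain background — no sensors, no annotation — and
then asks which movements actually discriminate the spoken sound
categories (for example, lexical tones).

## What the pipeline does

1. **Token segmentation** (`facekin.audio`). The short-time energy of the
   audio track (window 400 samples ≈ 25 ms at 16 kHz, step 1) is
   median-filtered (order 5) and thresholded at 20% of its maximum;
   contiguous supra-threshold runs are utterances, runs shorter than 35%
   of the longest are discarded as noise (keystrokes, coughs), and each
   surviving cluster is mapped to video frames and padded with a
   10-frame buffer (~0.33 s at 29.97 fps).
2. **Keypoint detection** (`facekin.detect`), on the first frame of each
   token. A face box is found first; part detectors then localize the
   nose, the eye pair, the left eye, and the mouth. Each box detector is
   swept over a merge-threshold schedule (1–150 in steps of 10, with
   adaptive halving for the eye pair) until exactly one box remains.
   Part-specific refiners produce four keypoints: the nose tip (mean of
   the lower nose edge from an edge-based active contour, ≤500
   iterations, smoothness 2), the medial left-eyebrow point (arg-max row
   of three fused evidence maps: patch-contrast color, Canny edges in
   HSV, and a Chan–Vese contour boundary, ≤400 iterations), and the
   upper/lower lip midpoints (HSV H/S thresholding with a 48% ON rule,
   largest component, convex hull dilated by a radius-7 disk, refined by
   an edge-based active contour and split at the oral commissures).
3. **Tracking** (`facekin.track`). A pyramidal Kanade–Lucas–Tomasi
   tracker (3 levels, 31×31 window) carries the four points through the
   token with subpixel precision. Translational head motion is then
   removed from the eyebrow and lip tracks by subtracting the nose
   displacement.
4. **Feature extraction** (`facekin.features`). Each token becomes 33
   features — per region (head, eyebrow, lips): maximum raising and
   lowering displacement, mean absolute and total path distance, the
   relative times of the displacement and velocity extrema, and maximum
   rising/falling velocity and absolute acceleration — computed from the
   vertical displacement profile d(t) = y(0) − y(t) (lips: the aperture
   g(t) = y_lower − y_upper), with v = Δd·fps and a = Δ²d·fps². All
   distances are normalized by the head size h = the perpendicular
   distance from the nose tip to the inter-eye line, and can be
   converted to millimetres given the physical head size.
5. **Feature significance** (`facekin.significance`). Each class is
   tested one-vs-all: balanced bootstrap samples (r = 500 per class,
   repeated N = 300 times) feed random forests (t = 500 trees, minimum
   leaf 20, √p features per split) with out-of-bag (OOB) bookkeeping.
   Per feature, the column is permuted repeatedly, OOB votes are
   recomputed, and the pooled 2×2 permuted/unpermuted ×
   correct/incorrect contingency table is tested with Pearson's χ²;
   median p-values across bootstrap repeats are Benjamini–Hochberg
   corrected and features with adjusted p < 0.05 are significant. A
   post-hoc table compares class-conditional means of the significant
   features.

Because recorded speaker videos cannot be bundled, `facekin.synth`
renders schematic talking faces (with analytic ground-truth keypoint
tracks and contours), token-burst audio, analytic trajectories with
closed-form feature values, and labeled feature tables with planted
effects — every stage is testable end to end without external data.

## A worked example

```python
import numpy as np
import facekin as fk

audio, _ = fk.synth_token_audio(n_tokens=2, token_length_s=0.8, gap_s=1.0,
                                rate=16000, peak=1.0, noise_floor=0.01, seed=3)
n_frames = int(np.ceil(audio.duration * 29.97))
video = fk.render_face_video(fk.FaceSceneSpec.scripted(
    height=540, width=960, n_frames=n_frames))

result = fk.run_token_pipeline(video, audio)
print(result.features[["token_id", "f05_eyebrow_max_raise",
                       "f09_lips_max_raise", "normalizer_px"]])
```

prints

```
 token_id  f05_eyebrow_max_raise  f09_lips_max_raise  normalizer_px
        0                 0.1489              0.2066        76.5692
        1                 0.0000              0.0000        76.3385
```

Two tokens were cut from the recording by their audio energy. During
token 0 the scripted face raises its eyebrow by ~15% of the head size
and opens the lips by ~21%; during token 1 the articulators only return
toward rest, so the raising/opening maxima are zero. The normalizer
(~76 px) is the nose-to-eye-line distance used to make features
comparable across speakers and camera distances.

The `examples/` directory holds one short script per capability
(segmentation, detection, tracking/compensation, the full pipeline, and
forest-based feature significance); each prints the numbers it computes
and what they mean. A thin CLI mirrors the stages:
`facekin segment|detect|track|features|analyze|synth|run --help`.

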