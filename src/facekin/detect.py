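"""Face region-of-interest detection and keypoint selection.

On the first frame of a token the face is localized, then part-specific
detectors refine the nose, left eye/eyebrow and lips, and four keypoints
are derived for tracking: the nose tip (proxy for head motion), the
medial point of the left eyebrow's superciliary ridge, and the midpoints
of the upper and lower lip.

The coarse localization stage is a pluggable *box detector*.  The
reference method uses pretrained cascade classifiers whose
merge-threshold parameter is swept from a low value upward until exactly
one bounding box is returned; that adaptive schedule is implemented here
(`adaptive_cascade_detect`) independently of what produces the raw
boxes.  The bundled `GeometryDetector` finds the regions from color and
connectivity cues and is tuned to the schematic faces produced by
`facekin.synth`; cascade model files for real video can be plugged in by
implementing the same two-method interface.

Coordinates are 0-based pixels, origin at the top-left corner, x
rightward and y downward.  A box covers columns x..x+w-1 and rows
y..y+h-1 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image, dilation, disk, erosion
from skimage.segmentation import (
    inverse_gaussian_gradient,
    morphological_chan_vese,
    morphological_geodesic_active_contour,
)

from .config import DetectorConfig
from .errors import (
    DetectionFailureError,
    InvalidArgumentError,
    SegmentationFailureError,
)

__all__ = [
    "BoundingBox",
    "KeypointSet",
    "BoxDetector",
    "GeometryDetector",
    "DetectionResult",
    "adaptive_cascade_detect",
    "detect_nose_tip",
    "detect_left_eye_box",
    "eyebrow_search_region",
    "eyebrow_probability_maps",
    "extract_eyebrow_ridge",
    "segment_lips",
    "select_keypoints",
    "detect_keypoints",
]

DETECTOR_KINDS = ("face", "eye_pair", "left_eye", "nose", "mouth")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: top-left corner (x, y), extent (w, h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise InvalidArgumentError("box extent must be positive")

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + (self.w - 1) / 2.0, self.y + (self.h - 1) / 2.0)

    def clip(self, height: int, width: int) -> "BoundingBox":
        x0 = max(0, self.x)
        y0 = max(0, self.y)
        x1 = min(width, self.x + self.w)
        y1 = min(height, self.y + self.h)
        if x1 <= x0 or y1 <= y0:
            raise InvalidArgumentError("box lies outside the image")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)

    def expand(self, fraction: float, height: int, width: int) -> "BoundingBox":
        dx = int(round(self.w * fraction))
        dy = int(round(self.h * fraction))
        return BoundingBox(self.x - dx, self.y - dy,
                           self.w + 2 * dx, self.h + 2 * dy).clip(height, width)

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)


@dataclass
class KeypointSet:
    """The four reference-frame keypoints, (x, y) pixel coordinates."""

    nose_tip: tuple[float, float]
    eyebrow_mid: tuple[float, float]
    upper_lip: tuple[float, float]
    lower_lip: tuple[float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.nose_tip, self.eyebrow_mid,
                         self.upper_lip, self.lower_lip], dtype=float)

    def validate_upright(self) -> None:
        if not (self.eyebrow_mid[1] < self.nose_tip[1] < self.lower_lip[1]):
            raise InvalidArgumentError(
                "keypoints violate the upright-face ordering "
                "(eyebrow above nose above lower lip)")


class BoxDetector(Protocol):
    """Interface for pluggable box detectors (cascade stand-in).

    ``detect`` returns candidate boxes in full-image coordinates for one
    region kind at one merge threshold, optionally restricted to a
    search region.  Higher merge thresholds must not increase the number
    of raw detections for the adaptive schedule to terminate.
    """

    def detect(self, image: np.ndarray, kind: str, merge_threshold: int,
               region: BoundingBox | None = None) -> list[BoundingBox]:
        ...


def _mask_boxes(mask: np.ndarray, min_area: float,
                offset: tuple[int, int]) -> list[BoundingBox]:
    lab = label(mask)
    boxes = []
    for prop in regionprops(lab):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        boxes.append(BoundingBox(c0 + offset[0], r0 + offset[1], c1 - c0, r1 - r0))
    boxes.sort(key=lambda b: -b.w * b.h)
    return boxes


class GeometryDetector:
    """Color/connectivity box detector for schematic frontal faces.

    Finds each region kind by thresholding HSV color bands (skin-tone
    face including a darker-shaded nose, near-white sclera, crimson
    lips) and taking connected components whose pixel area is at least
    ``merge_threshold`` times a resolution-dependent unit, so that
    raising the merge threshold monotonically prunes detections, mirroring
    cascade merge behavior.  Tuned for the palette of the bundled
    schematic renderer; for real video substitute a cascade-based
    detector implementing the same interface.
    """

    #: HSV rules per kind: (h_lo, h_hi, s_lo, s_hi, v_lo, v_hi); hue may wrap.
    RULES = {
        "face": (0.02, 0.12, 0.20, 0.60, 0.55, 1.01),
        "eye": (0.00, 1.01, 0.00, 0.15, 0.90, 1.01),
        "nose": (0.02, 0.12, 0.45, 1.01, 0.62, 0.86),
        "mouth": (0.85, 0.02, 0.60, 1.01, 0.10, 1.01),
    }
    AREA_UNIT_FRACTION = 1e-5  # of the full-image pixel count, per threshold step

    def _mask(self, hsv: np.ndarray, kind: str) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        h_lo, h_hi, s_lo, s_hi, v_lo, v_hi = self.RULES[kind]
        if h_lo <= h_hi:
            hue_ok = (h >= h_lo) & (h < h_hi)
        else:  # wrap-around hue band (red)
            hue_ok = (h >= h_lo) | (h < h_hi)
        return hue_ok & (s >= s_lo) & (s < s_hi) & (v >= v_lo) & (v < v_hi)

    def detect(self, image: np.ndarray, kind: str, merge_threshold: int,
               region: BoundingBox | None = None) -> list[BoundingBox]:
        if kind not in DETECTOR_KINDS:
            raise InvalidArgumentError(f"unknown detector kind {kind!r}")
        height, width = image.shape[:2]
        if region is not None:
            region = region.clip(height, width)
            crop = image[region.slices()]
            offset = (region.x, region.y)
        else:
            crop = image
            offset = (0, 0)
        hsv = rgb2hsv(crop)
        rule_kind = {"face": "face", "nose": "nose", "mouth": "mouth",
                     "eye_pair": "eye", "left_eye": "eye"}[kind]
        mask = self._mask(hsv, rule_kind)
        unit = max(1.0, height * width * self.AREA_UNIT_FRACTION)
        boxes = _mask_boxes(mask, max(merge_threshold, 1) * unit, offset)
        if kind == "eye_pair" and len(boxes) > 1:
            # the pair detector reports one box spanning both eyes
            x0 = min(b.x for b in boxes)
            y0 = min(b.y for b in boxes)
            x1 = max(b.x + b.w for b in boxes)
            y1 = max(b.y + b.h for b in boxes)
            boxes = [BoundingBox(x0, y0, x1 - x0, y1 - y0)]
        return boxes


def adaptive_cascade_detect(image: np.ndarray, kind: str, detector: BoxDetector,
                            config: DetectorConfig | None = None,
                            region: BoundingBox | None = None) -> BoundingBox:
    """Sweep the merge-threshold schedule until exactly one box remains.

    The merge threshold starts low (many raw detections) and is raised
    until the detector returns a unique box inside the search region; for
    adaptive schedules (eye pair) the increment is halved, with a floor
    of 1, whenever the detection count does not decrease between
    consecutive thresholds.  Exhausting the schedule without a unique
    box raises :class:`DetectionFailureError`.
    """
    config = config or DetectorConfig()
    if kind not in DETECTOR_KINDS:
        raise InvalidArgumentError(f"unknown detector kind {kind!r}")
    schedule = config.schedule_for(kind)
    t = schedule.start
    step = schedule.step
    prev_count: int | None = None
    while t <= schedule.stop:
        boxes = detector.detect(image, kind, t, region=region)
        if len(boxes) == 1:
            return boxes[0]
        if schedule.adaptive and prev_count is not None and len(boxes) >= prev_count:
            step = max(1, step // 2)
        prev_count = len(boxes)
        t += step
    raise DetectionFailureError(kind)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = label(mask)
    if lab.max() == 0:
        raise SegmentationFailureError("mask is empty")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _lower_edge_contour(mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Bottom-most mask pixel of every occupied column, as (x, y) points."""
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size < 2:
        raise SegmentationFailureError("contour collapsed (< 2 points)")
    ys = mask.shape[0] - 1 - np.argmax(mask[::-1, cols], axis=0)
    return np.column_stack([cols + offset[0], ys + offset[1]]).astype(float)


def _edge_snap(gray: np.ndarray, init_mask: np.ndarray, iterations: int,
               smoothing: int) -> np.ndarray:
    """Edge-based active contour: shrink an initial mask onto intensity
    edges (geodesic model, negative balloon force)."""
    gimage = inverse_gaussian_gradient(gray, alpha=1000.0, sigma=1.0)
    out = morphological_geodesic_active_contour(
        gimage, num_iter=iterations, init_level_set=init_mask.astype(np.int8),
        smoothing=smoothing, balloon=-1, threshold=0.5)
    return out.astype(bool)


def detect_nose_tip(image: np.ndarray, face_box: BoundingBox,
                    config: DetectorConfig | None = None,
                    detector: BoxDetector | None = None,
                    ) -> tuple[tuple[float, float], np.ndarray]:
    """Locate the nose box, refine its lower edge with an edge-based
    active contour, and return (keypoint, contour).

    The keypoint is the coordinate-wise mean of the lower-nose-edge
    contour; the nose tip sits on this well-defined edge, making it a
    stable proxy for head translation.
    """
    config = config or DetectorConfig()
    detector = detector or GeometryDetector()
    height, width = image.shape[:2]
    nose_box = adaptive_cascade_detect(image, "nose", detector, config, region=face_box)
    crop_box = nose_box.expand(0.30, height, width)
    crop = image[crop_box.slices()]
    gray = rgb2gray(crop)
    init = np.zeros(crop.shape[:2], dtype=bool)
    init[nose_box.y - crop_box.y: nose_box.y - crop_box.y + nose_box.h,
         nose_box.x - crop_box.x: nose_box.x - crop_box.x + nose_box.w] = True
    mask = _edge_snap(gray, init, config.nose_ac_iters, config.nose_ac_smoothness)
    if not mask.any():
        raise SegmentationFailureError("nose active contour collapsed")
    mask = _largest_component(mask)
    contour = _lower_edge_contour(mask, (crop_box.x, crop_box.y))
    keypoint = (float(contour[:, 0].mean()), float(contour[:, 1].mean()))
    return keypoint, contour


def detect_left_eye_box(image: np.ndarray, face_box: BoundingBox,
                        config: DetectorConfig | None = None,
                        detector: BoxDetector | None = None) -> BoundingBox:
    """Find the left-eye box via the eye pair.

    The eye-pair box is detected first (adaptive schedule) because it
    produces far fewer false positives; left-eye candidates are then
    scored by the Euclidean distance from the eye-pair box's top-left
    corner to the candidate's top-left corner and the closest wins.
    """
    config = config or DetectorConfig()
    detector = detector or GeometryDetector()
    pair_box = adaptive_cascade_detect(image, "eye_pair", detector, config,
                                       region=face_box)
    schedule = config.left_eye_schedule
    t = schedule.start
    candidates: list[BoundingBox] = []
    while t <= schedule.stop:
        candidates = detector.detect(image, "left_eye", t, region=face_box)
        if candidates:
            break
        t += schedule.step
    if not candidates:
        raise DetectionFailureError("left_eye")
    dist = [np.hypot(b.x - pair_box.x, b.y - pair_box.y) for b in candidates]
    return candidates[int(np.argmin(dist))]


def eyebrow_search_region(eye_box: BoundingBox, height: int, width: int) -> BoundingBox:
    """Eye box plus the band directly above it (same height)."""
    return BoundingBox(eye_box.x, eye_box.y - eye_box.h,
                       eye_box.w, 2 * eye_box.h).clip(height, width)


def eyebrow_probability_maps(image: np.ndarray, eye_box: BoundingBox,
                             config: DetectorConfig | None = None,
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three per-pixel eyebrow-evidence maps over the search region.

    1. *Color*: the eyebrow is darker than the skin above it, so a
       P-by-P patch ending just above a pixel is compared with the patch
       starting at it; positive (brighter-above-darker-below) contrast
       scores the pixel.  P is 10% of the eye-box height (floored, at
       least 1).
    2. *Edge*: Canny edges of the HSV value channel, restricted to the
       top half of the region where the superciliary ridge must lie.
    3. *Contour*: the boundary of a region-based (Chan-Vese) active
       contour, run for at most ``eyebrow_ac_iters`` iterations from an
       eyebrow-box estimate (the eye box shifted up by 60% of its
       height).

    Maps are max-normalized to [0, 1] (all-zero maps stay zero) and
    returned in the region's own coordinates; see
    :func:`eyebrow_search_region` for the region placement.
    """
    config = config or DetectorConfig()
    height, width = image.shape[:2]
    region = eyebrow_search_region(eye_box, height, width)
    crop = image[region.slices()]
    rh, rw = crop.shape[:2]
    P = int(np.floor(config.eyebrow_patch_fraction * eye_box.h))
    if P < 1:
        if eye_box.h < 2:
            raise InvalidArgumentError("eye box too small for patch comparison")
        P = 1
    if rh < 2 * P + 1 or rw < P:
        raise InvalidArgumentError("degenerate eyebrow search region")
    gray = rgb2gray(crop)

    # color contrast: integral-image block sums of P x P patches
    csum = np.zeros((rh + 1, rw + 1))
    csum[1:, 1:] = gray.cumsum(axis=0).cumsum(axis=1)

    def block(y0, x0):  # sum over rows [y0, y0+P), cols [x0, x0+P)
        return (csum[y0 + P, x0 + P] - csum[y0, x0 + P]
                - csum[y0 + P, x0] + csum[y0, x0])

    color = np.zeros((rh, rw))
    ys = np.arange(P, rh - P)
    xs = np.arange(0, rw - P + 1)
    if ys.size and xs.size:
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        above = block(yy - P, xx)
        below = block(yy, xx)
        contrast = np.clip(above - below, 0.0, None)
        # integral-image rounding residue is not contrast
        contrast[contrast < 1e-8 * P * P] = 0.0
        color[P:rh - P, 0:rw - P + 1] = contrast

    hsv = rgb2hsv(crop)
    edge = canny(hsv[..., 2]).astype(float)
    edge[rh // 2:, :] = 0.0

    shift = int(round(config.eyebrow_shift_fraction * eye_box.h))
    init = np.zeros((rh, rw), dtype=bool)
    top = eye_box.y - region.y - shift
    init[max(0, top): max(0, top) + eye_box.h, :] = True
    cv = morphological_chan_vese(gray, num_iter=config.eyebrow_ac_iters,
                                 init_level_set=init.astype(np.int8), smoothing=1)
    cv = cv.astype(bool)
    if cv.any() and (~cv).any():
        if gray[cv].mean() > gray[~cv].mean():
            cv = ~cv  # the eyebrow is the darker phase
    boundary = cv & ~erosion(cv)
    contour_map = boundary.astype(float)

    def norm(m):
        peak = m.max()
        return m / peak if peak > 0 else m

    return norm(color), norm(edge), norm(contour_map)


def extract_eyebrow_ridge(maps: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    """Fuse the three evidence maps additively and return the ridge.

    Per-row totals of the summed maps are compared and the arg-max row
    is taken as the superciliary ridge line (ties break to the upper
    row); the contour is that row across the region width, in region
    coordinates.  Row totals are pooled with a [0.5, 1, 0.5] tent
    kernel before the arg-max: the three evidence sources mark the same
    physical edge on pixel rows that can differ by one (Canny marks one
    side of an edge, a contour boundary the other), and pooling keeps
    that split evidence from losing to a weaker but pixel-aligned row,
    while a single winning row still wins outright.
    """
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise InvalidArgumentError("probability maps must share one shape")
    total = maps[0] + maps[1] + maps[2]
    raw = total.sum(axis=1)
    row_sums = raw + 0.5 * (np.concatenate([raw[1:], [0.0]])
                            + np.concatenate([[0.0], raw[:-1]]))
    if not np.any(row_sums > 0):
        raise SegmentationFailureError("no eyebrow evidence in any row")
    ridge_row = int(np.argmax(row_sums))  # argmax returns the first (upper) max
    xs = np.arange(total.shape[1], dtype=float)
    return np.column_stack([xs, np.full_like(xs, float(ridge_row))])


def segment_lips(image: np.ndarray, face_box: BoundingBox,
                 config: DetectorConfig | None = None,
                 detector: BoxDetector | None = None,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment the lips and split their outline at the oral commissures.

    The mouth box is found by the cascade schedule, its surroundings are
    converted to HSV, and the H and S channels are binarized (Otsu).  If
    both channels turn ON more than ``lip_on_fraction`` (48%) of the
    pixels, the masks are intersected; otherwise the dominant (more ON
    pixels) channel's mask is used.  The largest connected component is
    kept, its convex hull dilated by a radius-7 disk, and an edge-based
    active contour shrinks that initialization back onto the lip
    boundary.  Returns (full-image lip mask, upper contour, lower
    contour); contours are the per-column extremal mask pixels, split at
    the leftmost/rightmost occupied columns.
    """
    config = config or DetectorConfig()
    detector = detector or GeometryDetector()
    height, width = image.shape[:2]
    mouth_box = adaptive_cascade_detect(image, "mouth", detector, config,
                                        region=face_box)
    region = mouth_box.expand(0.15, height, width)
    crop = image[region.slices()]
    hsv = rgb2hsv(crop)
    masks = {}
    for idx, name in ((0, "h"), (1, "s")):
        channel = hsv[..., idx]
        try:
            thr = threshold_otsu(channel)
        except ValueError:  # constant channel
            thr = np.inf
        masks[name] = channel > thr
    frac_h = masks["h"].mean()
    frac_s = masks["s"].mean()
    if frac_h > config.lip_on_fraction and frac_s > config.lip_on_fraction:
        mask = masks["h"] & masks["s"]
    else:
        mask = masks["h"] if masks["h"].sum() >= masks["s"].sum() else masks["s"]
    if not mask.any():
        raise SegmentationFailureError("lip thresholding produced an empty mask")
    mask = _largest_component(mask)
    hull = convex_hull_image(mask)
    init = dilation(hull, disk(config.lip_dilate_radius))
    gray = rgb2gray(crop)
    refined = _edge_snap(gray, init, config.lip_ac_iters, config.lip_ac_smoothness)
    if not refined.any():
        raise SegmentationFailureError("lip active contour collapsed")
    refined = _largest_component(refined)

    cols = np.flatnonzero(refined.any(axis=0))
    if cols.size < 2:
        raise SegmentationFailureError("lip mask collapsed (< 2 columns)")
    top = np.argmax(refined[:, cols], axis=0)
    bottom = refined.shape[0] - 1 - np.argmax(refined[::-1, cols], axis=0)
    upper = np.column_stack([cols + region.x, top + region.y]).astype(float)
    lower = np.column_stack([cols + region.x, bottom + region.y]).astype(float)

    full_mask = np.zeros((height, width), dtype=bool)
    full_mask[region.slices()] = refined
    return full_mask, upper, lower


def select_keypoints(nose_contour: np.ndarray, eyebrow_contour: np.ndarray,
                     upper_lip_contour: np.ndarray,
                     lower_lip_contour: np.ndarray) -> KeypointSet:
    """Reduce the four contours to the four tracked keypoints.

    Nose tip and eyebrow mid-point are the coordinate-wise means of
    their contours.  The lip keypoints sit at the column midway between
    the oral commissures (the extreme columns of the lip outline): the
    upper contour's point there approximates the Cupid's bow, the lower
    contour's point the lower-lip midpoint.
    """
    for name, contour in (("nose", nose_contour), ("eyebrow", eyebrow_contour),
                          ("upper lip", upper_lip_contour),
                          ("lower lip", lower_lip_contour)):
        if contour is None or len(contour) == 0:
            raise SegmentationFailureError(f"missing {name} contour")
    nose_tip = tuple(np.asarray(nose_contour, dtype=float).mean(axis=0))
    eyebrow_mid = tuple(np.asarray(eyebrow_contour, dtype=float).mean(axis=0))
    xs = upper_lip_contour[:, 0]
    mid_col = (xs.min() + xs.max()) / 2.0
    upper = upper_lip_contour[np.argmin(np.abs(upper_lip_contour[:, 0] - mid_col))]
    lower = lower_lip_contour[np.argmin(np.abs(lower_lip_contour[:, 0] - mid_col))]
    return KeypointSet(nose_tip=(float(nose_tip[0]), float(nose_tip[1])),
                       eyebrow_mid=(float(eyebrow_mid[0]), float(eyebrow_mid[1])),
                       upper_lip=(float(upper[0]), float(upper[1])),
                       lower_lip=(float(lower[0]), float(lower[1])))


@dataclass
class DetectionResult:
    """Everything detected on a token's reference frame."""

    keypoints: KeypointSet
    eye_left: tuple[float, float]
    eye_right: tuple[float, float]
    boxes: dict[str, BoundingBox]
    contours: dict[str, np.ndarray]


def _eye_centers(image: np.ndarray, face_box: BoundingBox, left_eye: BoundingBox,
                 config: DetectorConfig, detector: BoxDetector,
                 ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Centers of the two eyes, for the head-size normalizer.

    Taken from the eye-candidate boxes inside the face; if only one eye
    is found, the other is mirrored across the face's vertical midline.
    """
    schedule = config.left_eye_schedule
    t = schedule.start
    candidates: list[BoundingBox] = []
    while t <= schedule.stop and not candidates:
        candidates = detector.detect(image, "left_eye", t, region=face_box)
        t += schedule.step
    centers = sorted((b.center for b in candidates), key=lambda c: c[0])
    if len(centers) >= 2:
        return centers[0], centers[-1]
    cx = face_box.x + (face_box.w - 1) / 2.0
    only = centers[0] if centers else left_eye.center
    mirrored = (2 * cx - only[0], only[1])
    return tuple(sorted([only, mirrored], key=lambda c: c[0]))  # type: ignore[return-value]


def detect_keypoints(image: np.ndarray, config: DetectorConfig | None = None,
                     detector: BoxDetector | None = None) -> DetectionResult:
    """Full reference-frame detection: face, nose, eye/eyebrow, lips.

    Runs every part-specific detector and returns the keypoint set
    together with the intermediate boxes and contours (useful for
    overlays and error analysis).
    """
    config = config or DetectorConfig()
    detector = detector or GeometryDetector()
    height, width = image.shape[:2]
    face_box = adaptive_cascade_detect(image, "face", detector, config)
    nose_tip, nose_contour = detect_nose_tip(image, face_box, config, detector)
    eye_box = detect_left_eye_box(image, face_box, config, detector)
    region = eyebrow_search_region(eye_box, height, width)
    maps = eyebrow_probability_maps(image, eye_box, config)
    ridge_local = extract_eyebrow_ridge(maps)
    ridge = ridge_local + np.array([region.x, region.y], dtype=float)
    lip_mask, upper_lip, lower_lip = segment_lips(image, face_box, config, detector)
    keypoints = select_keypoints(nose_contour, ridge, upper_lip, lower_lip)
    eye_left, eye_right = _eye_centers(image, face_box, eye_box, config, detector)
    return DetectionResult(
        keypoints=keypoints,
        eye_left=eye_left,
        eye_right=eye_right,
        boxes={"face": face_box, "left_eye": eye_box},
        contours={"nose": nose_contour, "eyebrow": ridge,
                  "upper_lip": upper_lip, "lower_lip": lower_lip},
    )
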