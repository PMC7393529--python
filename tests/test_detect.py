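"""Region-of-interest detection: adaptive schedules, part refiners,
keypoint selection, accuracy on rendered ground truth."""

import numpy as np
import pytest

import facekin as fk
from facekin.config import DetectorConfig
from facekin.detect import (
    BoundingBox,
    adaptive_cascade_detect,
    detect_left_eye_box,
    detect_nose_tip,
    extract_eyebrow_ridge,
    eyebrow_probability_maps,
    eyebrow_search_region,
    segment_lips,
    select_keypoints,
)
from facekin.errors import (
    DetectionFailureError,
    InvalidArgumentError,
    SegmentationFailureError,
)


class _StubDetector:
    """Scriptable detector: n_boxes(threshold) -> number of candidates."""

    def __init__(self, n_boxes):
        self.n_boxes = n_boxes
        self.calls = []

    def detect(self, image, kind, merge_threshold, region=None):
        self.calls.append(merge_threshold)
        n = self.n_boxes(merge_threshold)
        return [BoundingBox(10 * i, 10, 5, 5) for i in range(n)]


_IMG = np.zeros((50, 50, 3), dtype=np.uint8)


class TestAdaptiveSchedule:
    def test_immediate_unique_box_returns_first(self):
        stub = _StubDetector(lambda t: 1)
        box = adaptive_cascade_detect(_IMG, "face", stub)
        assert box == BoundingBox(0, 10, 5, 5)
        assert stub.calls == [1]

    def test_count_decays_with_threshold(self):
        # ceil(20/t) candidates: 20 at t=1, 2 at t=11, 1 at t=21
        stub = _StubDetector(lambda t: -(-20 // t))
        adaptive_cascade_detect(_IMG, "face", stub)
        assert stub.calls == [1, 11, 21]

    def test_exhausted_schedule_raises_with_kind(self):
        stub = _StubDetector(lambda t: 2)
        with pytest.raises(DetectionFailureError, match="nose"):
            adaptive_cascade_detect(_IMG, "nose", stub)

    def test_adaptive_step_halves_when_count_stalls(self):
        # eye-pair schedule adapts: counts that never decrease halve the
        # step from 10 down to 1
        stub = _StubDetector(lambda t: 3)
        with pytest.raises(DetectionFailureError):
            adaptive_cascade_detect(_IMG, "eye_pair", stub)
        steps = np.diff(stub.calls)
        assert steps[0] == 10
        assert 5 in steps and 1 in steps
        assert all(a >= b for a, b in zip(steps, steps[1:]))

    def test_unknown_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            adaptive_cascade_detect(_IMG, "ear", _StubDetector(lambda t: 1))


class TestLeftEye:
    def test_minimum_corner_distance_wins(self):
        # eye-pair box at (10, 10); candidates at corner distances 5, 12, 40
        class Stub:
            def detect(self, image, kind, t, region=None):
                if kind == "eye_pair":
                    return [BoundingBox(10, 10, 30, 8)]
                return [BoundingBox(10 + 3, 10 + 4, 6, 6),    # distance 5
                        BoundingBox(10 + 12, 10, 6, 6),        # distance 12
                        BoundingBox(10 + 24, 10 + 32, 6, 6)]   # distance 40

        box = detect_left_eye_box(_IMG, BoundingBox(0, 0, 50, 50),
                                  detector=Stub())
        assert (box.x, box.y) == (13, 14)

    def test_single_candidate_returned_unchanged(self):
        class Stub:
            def detect(self, image, kind, t, region=None):
                if kind == "eye_pair":
                    return [BoundingBox(10, 10, 30, 8)]
                return [BoundingBox(12, 11, 6, 6)]

        box = detect_left_eye_box(_IMG, BoundingBox(0, 0, 50, 50),
                                  detector=Stub())
        assert box == BoundingBox(12, 11, 6, 6)

    def test_no_candidates_raises(self):
        class Stub:
            def detect(self, image, kind, t, region=None):
                if kind == "eye_pair":
                    return [BoundingBox(10, 10, 30, 8)]
                return []

        with pytest.raises(DetectionFailureError, match="left_eye"):
            detect_left_eye_box(_IMG, BoundingBox(0, 0, 50, 50), detector=Stub())

    def test_geometry_detector_finds_image_left_eye(self, scripted_video):
        frame = scripted_video[0]
        face = adaptive_cascade_detect(frame, "face", fk.GeometryDetector())
        box = detect_left_eye_box(frame, face)
        gt_left, _ = scripted_video.eye_centers(0)
        cx, cy = box.center
        assert abs(cx - gt_left[0]) < 3 and abs(cy - gt_left[1]) < 3


class TestEyebrow:
    def test_uniform_region_has_zero_color_map(self):
        img = np.full((60, 60, 3), 180, dtype=np.uint8)
        color, _, _ = eyebrow_probability_maps(img, BoundingBox(10, 30, 20, 20))
        assert np.all(color == 0)

    def test_bright_above_dark_boundary_maximizes_color_map(self):
        # value 200 above row 12, value 40 below, inside the search band
        img = np.full((60, 60, 3), 200, dtype=np.uint8)
        img[12:, :] = 40
        eye_box = BoundingBox(10, 20, 30, 20)   # region rows 0..39, P = 2
        color, _, _ = eyebrow_probability_maps(img, eye_box)
        rows = color.sum(axis=1)
        assert rows.argmax() == 12

    def test_ridge_is_argmax_row(self):
        maps = tuple(np.zeros((10, 6)) for _ in range(3))
        maps[0][7, :] = 1.0
        contour = extract_eyebrow_ridge(maps)
        assert np.all(contour[:, 1] == 7)
        assert len(contour) == 6

    def test_ridge_tie_breaks_upward(self):
        a = np.zeros((12, 5))
        a[3, :] = 0.5
        a[7, :] = 0.82
        a[9, :] = 0.82
        contour = extract_eyebrow_ridge((a, np.zeros_like(a), np.zeros_like(a)))
        assert contour[0, 1] == 7

    def test_all_zero_maps_raise(self):
        z = np.zeros((8, 8))
        with pytest.raises(SegmentationFailureError):
            extract_eyebrow_ridge((z, z, z))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            extract_eyebrow_ridge((np.zeros((4, 4)), np.zeros((4, 5)),
                                   np.zeros((4, 4))))

    def test_search_region_is_eye_box_plus_band_above(self):
        region = eyebrow_search_region(BoundingBox(40, 60, 20, 16), 200, 200)
        assert (region.x, region.y, region.w, region.h) == (40, 44, 20, 32)

    def test_ridge_on_render_matches_brow_top_edge(self, scripted_video):
        frame = scripted_video[0]
        face = adaptive_cascade_detect(frame, "face", fk.GeometryDetector())
        eye_box = detect_left_eye_box(frame, face)
        region = eyebrow_search_region(eye_box, *frame.shape[:2])
        maps = eyebrow_probability_maps(frame, eye_box)
        ridge = extract_eyebrow_ridge(maps)
        gt = scripted_video.contours(0)["eyebrow"]
        assert abs((ridge[0, 1] + region.y) - gt[0, 1]) <= 2


class TestLips:
    def test_dice_overlap_against_ground_truth(self, scripted_video,
                                               scripted_detection):
        mask, upper, lower = segment_lips(scripted_video[0],
                                          scripted_detection.boxes["face"])
        gt = scripted_video.lip_mask(0)
        dice = 2 * (mask & gt).sum() / (mask.sum() + gt.sum())
        assert dice >= 0.8

    def test_upper_contour_above_lower(self, scripted_video, scripted_detection):
        _, upper, lower = segment_lips(scripted_video[0],
                                       scripted_detection.boxes["face"])
        assert np.all(upper[:, 1] <= lower[:, 1])
        assert np.array_equal(upper[:, 0], lower[:, 0])


class TestSelectKeypoints:
    _line = np.array([[0.0, 5.0], [10.0, 5.0]])

    def test_single_point_contour_is_identity(self):
        pt = np.array([[3.0, 4.0]])
        kp = select_keypoints(pt, pt - [0, 3], self._line, self._line + [0, 2])
        assert kp.nose_tip == (3.0, 4.0)

    def test_mean_of_contour(self):
        contour = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 6.0]])
        kp = select_keypoints(contour, contour - [0, 10],
                              self._line, self._line + [0, 2])
        assert kp.nose_tip == (2.0, 2.0)

    def test_lip_points_at_commissure_midpoint_column(self):
        xs = np.arange(11.0)
        upper = np.column_stack([xs, 10 - 0.1 * (xs - 5) ** 2])
        lower = np.column_stack([xs, 20 + 0.1 * (xs - 5) ** 2])
        kp = select_keypoints(self._line, self._line - [0, 8], upper, lower)
        assert kp.upper_lip == (5.0, 10.0)
        assert kp.lower_lip == (5.0, 20.0)

    def test_missing_contour_identifies_region(self):
        with pytest.raises(SegmentationFailureError, match="eyebrow"):
            select_keypoints(self._line, np.empty((0, 2)),
                             self._line, self._line)

    def test_exactly_four_keypoints(self, scripted_detection):
        assert scripted_detection.keypoints.as_array().shape == (4, 2)


class TestNoseTip:
    def test_symmetry_of_rendered_nose(self, scripted_video, scripted_detection):
        point, contour = detect_nose_tip(scripted_video[0],
                                         scripted_detection.boxes["face"])
        axis = scripted_video.keypoint_tracks["nose"][0][0]
        assert abs(point[0] - axis) <= 1.0

    def test_within_one_percent_of_ground_truth(self, scripted_video,
                                                scripted_detection):
        point, _ = detect_nose_tip(scripted_video[0],
                                   scripted_detection.boxes["face"])
        err = fk.evaluate_landmark_error(point,
                                         scripted_video.contours(0)["nose"],
                                         (270, 480))
        assert err < 1.0


class TestFullDetection:
    def test_all_keypoints_within_one_percent(self, scripted_video,
                                              scripted_detection):
        contours = scripted_video.contours(0)
        kp = scripted_detection.keypoints
        for attr, name in [("nose_tip", "nose"), ("eyebrow_mid", "eyebrow"),
                           ("upper_lip", "upper_lip"), ("lower_lip", "lower_lip")]:
            err = fk.evaluate_landmark_error(getattr(kp, attr), contours[name],
                                             (270, 480))
            assert err < 1.0, f"{name}: {err:.3f}%"

    def test_upright_ordering(self, scripted_detection):
        scripted_detection.keypoints.validate_upright()

    def test_detection_is_deterministic(self, scripted_video):
        a = fk.detect_keypoints(scripted_video[0])
        b = fk.detect_keypoints(scripted_video[0])
        assert np.array_equal(a.keypoints.as_array(), b.keypoints.as_array())

    def test_keypoints_inside_face_region(self, scripted_detection):
        face = scripted_detection.boxes["face"]
        # eyebrow may sit in the band just above the face box
        for attr, slack in [("nose_tip", 0), ("eyebrow_mid", face.h // 4),
                            ("upper_lip", 0), ("lower_lip", 0)]:
            x, y = getattr(scripted_detection.keypoints, attr)
            assert face.x <= x <= face.x + face.w
            assert face.y - slack <= y <= face.y + face.h

    def test_eye_centers_match_render(self, scripted_video, scripted_detection):
        gt_l, gt_r = scripted_video.eye_centers(0)
        assert np.hypot(*(np.subtract(scripted_detection.eye_left, gt_l))) < 2
        assert np.hypot(*(np.subtract(scripted_detection.eye_right, gt_r))) < 2
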