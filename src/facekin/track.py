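"""Keypoint tracking and head-motion compensation.

The four reference-frame keypoints are tracked through the token with a
pyramidal Kanade-Lucas-Tomasi (KLT) tracker: a registration-based
method that finds, for each point, the translation between adjacent
frames that best explains the local intensity pattern, using spatial
intensity gradients in a fixed integration window.  A Gaussian image
pyramid (default 3 levels) lets the solver handle displacements larger
than half the window; estimates are refined coarse-to-fine with
iterative Gauss-Newton updates and bilinear subpixel sampling.

Translational head movement is then removed from the eyebrow and lip
trajectories by subtracting the head (nose) displacement, so those
tracks express articulatory motion relative to the head.  Rotations and
tilts are out of scope here and are best handled by registering frames
to a reference before tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .config import TrackerConfig
from .detect import KeypointSet
from .errors import InvalidArgumentError, InvalidStateError, TrackingFailureError

__all__ = [
    "KEYPOINT_NAMES",
    "TrajectorySet",
    "track_keypoints",
    "remove_head_translation",
    "evaluate_landmark_error",
]

#: Track order: the nose leads because compensation subtracts its motion.
KEYPOINT_NAMES = ("nose", "eyebrow", "upper_lip", "lower_lip")


@dataclass
class TrajectorySet:
    """Per-frame (x, y) positions of the four keypoints.

    ``positions[name]`` is a (T, 2) float array; ``lost[name]`` flags
    frames where the tracker lost the point and extrapolated instead.
    ``compensated`` records whether head translation has been removed
    from the eyebrow/lip tracks.
    """

    positions: dict[str, np.ndarray]
    fps: float
    compensated: bool = False
    lost: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(p) for p in self.positions.values()}
        if len(lengths) != 1:
            raise InvalidArgumentError("all tracks must have the same length")
        if not self.lost:
            self.lost = {name: np.zeros(len(p), dtype=bool)
                         for name, p in self.positions.items()}

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            positions={k: v.copy() for k, v in self.positions.items()},
            fps=self.fps, compensated=self.compensated,
            lost={k: v.copy() for k, v in self.lost.items()})


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        frame = frame @ np.array([0.2125, 0.7154, 0.0721])
    frame = np.asarray(frame, dtype=float)
    if frame.max() > 1.5:  # uint8-scaled input
        frame = frame / 255.0
    return frame


def _pyramid(gray: np.ndarray, levels: int, sigma: float) -> list[np.ndarray]:
    """Gaussian pyramid, finest level first; each level is presmoothed."""
    out = [gaussian_filter(gray, sigma)]
    for _ in range(1, levels):
        prev = out[-1]
        down = gaussian_filter(prev, 1.0)[::2, ::2]
        out.append(down)
    return out


def _sample(img: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    return map_coordinates(img, [ys, xs], order=1, mode="nearest")


def _lk_step(prev_lvl: np.ndarray, next_lvl: np.ndarray, p: np.ndarray,
             guess: np.ndarray, cfg: TrackerConfig) -> tuple[np.ndarray, bool]:
    """One pyramid level of forward-additive Lucas-Kanade for one point.

    ``p`` is the point in the previous frame (level coordinates),
    ``guess`` the current estimate in the next frame.  Returns the
    refined estimate and a validity flag (False when the point left the
    image)."""
    h, w = prev_lvl.shape
    half = cfg.window_size // 2
    rng = np.arange(-half, half + 1, dtype=float)
    wy, wx = np.meshgrid(rng, rng, indexing="ij")
    xs0 = p[0] + wx.ravel()
    ys0 = p[1] + wy.ravel()

    template = _sample(prev_lvl, xs0, ys0)
    # template gradients via central differences of bilinear samples
    gx = (_sample(prev_lvl, xs0 + 0.5, ys0) - _sample(prev_lvl, xs0 - 0.5, ys0))
    gy = (_sample(prev_lvl, xs0, ys0 + 0.5) - _sample(prev_lvl, xs0, ys0 - 0.5))
    gxx = np.dot(gx, gx)
    gyy = np.dot(gy, gy)
    gxy = np.dot(gx, gy)
    det = gxx * gyy - gxy * gxy
    if det < 1e-12:  # no texture: keep the coarse-level guess
        return guess, True

    q = guess.astype(float).copy()
    for _ in range(cfg.max_iterations):
        patch = _sample(next_lvl, q[0] + wx.ravel(), q[1] + wy.ravel())
        err = patch - template
        bx = np.dot(gx, err)
        by = np.dot(gy, err)
        dx = (gyy * bx - gxy * by) / det
        dy = (gxx * by - gxy * bx) / det
        q[0] -= dx
        q[1] -= dy
        if dx * dx + dy * dy < cfg.convergence_eps ** 2:
            break
    valid = (-half <= q[0] <= w - 1 + half) and (-half <= q[1] <= h - 1 + half)
    return q, valid


def _track_pair(prev_pyr: list[np.ndarray], next_pyr: list[np.ndarray],
                points: np.ndarray, cfg: TrackerConfig,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Track points from one frame to the next through the pyramid."""
    levels = len(prev_pyr)
    out = np.empty_like(points)
    ok = np.ones(len(points), dtype=bool)
    for i, p in enumerate(points):
        scale = 2.0 ** (levels - 1)
        guess = p / scale
        valid = True
        for lvl in range(levels - 1, -1, -1):
            p_lvl = p / (2.0 ** lvl)
            guess, valid = _lk_step(prev_pyr[lvl], next_pyr[lvl], p_lvl, guess, cfg)
            if not valid:
                break
            if lvl > 0:
                guess = guess * 2.0
        out[i] = guess
        ok[i] = valid
    return out, ok


def track_keypoints(video, keypoints: KeypointSet,
                    config: TrackerConfig | None = None,
                    fps: float = 29.97) -> TrajectorySet:
    """Track the four keypoints across all frames of a token.

    ``video`` is any indexable sequence of frames (H x W x 3 uint8 or
    grayscale float).  Points that leave the image are re-filled by
    extrapolating their last valid displacement and flagged in
    ``lost``; if every point is lost before frame 1 a
    :class:`TrackingFailureError` is raised.  Positions are subpixel.
    """
    config = config or TrackerConfig()
    config.validate()
    n_frames = len(video)
    if n_frames < 2:
        raise InvalidArgumentError("tracking needs at least 2 frames")

    pts = keypoints.as_array()
    n_pts = len(pts)
    positions = np.empty((n_frames, n_pts, 2), dtype=float)
    lost = np.zeros((n_frames, n_pts), dtype=bool)
    positions[0] = pts

    prev_pyr = _pyramid(_to_gray(np.asarray(video[0])), config.pyramid_levels,
                        config.smoothing_sigma)
    alive = np.ones(n_pts, dtype=bool)
    for t in range(1, n_frames):
        next_pyr = _pyramid(_to_gray(np.asarray(video[t])), config.pyramid_levels,
                            config.smoothing_sigma)
        new_pts, ok = _track_pair(prev_pyr, next_pyr, positions[t - 1], config)
        alive &= ok
        if t == 1 and not alive.any():
            raise TrackingFailureError("all keypoints lost before frame 1")
        # extrapolate lost points with their last valid displacement
        for i in range(n_pts):
            if not alive[i]:
                delta = (positions[t - 1, i] - positions[t - 2, i]
                         if t >= 2 else np.zeros(2))
                new_pts[i] = positions[t - 1, i] + delta
                lost[t, i] = True
        positions[t] = new_pts
        prev_pyr = next_pyr

    return TrajectorySet(
        positions={name: positions[:, i].copy()
                   for i, name in enumerate(KEYPOINT_NAMES)},
        fps=fps,
        compensated=False,
        lost={name: lost[:, i].copy() for i, name in enumerate(KEYPOINT_NAMES)},
    )


def remove_head_translation(trajectories: TrajectorySet) -> TrajectorySet:
    """Subtract head displacement from the eyebrow and lip tracks.

    For every non-nose keypoint, position(t) <- position(t) - (nose(t) -
    nose(0)); the nose track itself is unchanged.  Exact for global
    rigid translations: translating every frame by any vector leaves the
    compensated eyebrow/lip trajectories unchanged (up to tracker
    noise).  Applying this twice is an error, not a no-op.
    """
    if trajectories.compensated:
        raise InvalidStateError("trajectories are already head-compensated")
    out = trajectories.copy()
    nose = out.positions["nose"]
    head_disp = nose - nose[0]
    for name in KEYPOINT_NAMES:
        if name == "nose":
            continue
        out.positions[name] = out.positions[name] - head_disp
    out.compensated = True
    return out


def evaluate_landmark_error(auto_point, reference_curve: np.ndarray,
                            frame_size: tuple[int, int]) -> float:
    """Landmark error as a percentage of the frame height.

    The error of an automatically placed point against a reference curve
    (e.g. a manually traced or ground-truth contour) is the minimum
    Euclidean distance from the point to any curve point, divided by the
    frame height and expressed in percent.
    """
    curve = np.asarray(reference_curve, dtype=float)
    if curve.ndim != 2 or len(curve) == 0:
        raise InvalidArgumentError("reference curve must be a non-empty (N, 2) array")
    point = np.asarray(auto_point, dtype=float)
    dist = np.min(np.hypot(curve[:, 0] - point[0], curve[:, 1] - point[1]))
    height = frame_size[0]
    return float(dist / height * 100.0)
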