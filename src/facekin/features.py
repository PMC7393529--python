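"""Articulatory feature extraction.

Each token's compensated trajectories are reduced to 33 features in
three categories — distance, time, and kinematics — computed per region
of interest (head, eyebrow, lips) from a vertical displacement profile:

* head/eyebrow: d(t) = y(0) - y(t), so raising is positive (image y
  grows downward);
* lips: d(t) = g(t) - g(0) where g(t) = y_lower(t) - y_upper(t) is the
  inter-lip aperture, so opening is positive.

Velocity is the first difference of d scaled by fps (units/s) and
acceleration the second difference scaled by fps^2.  All distance and
kinematic features are normalized by the speaker's head size — the
perpendicular distance from the nose tip to the line joining the two
eyes — which removes camera-distance and head-size differences between
recordings; they can optionally be converted to millimetres by supplying
the physical head size.  Only vertical motion enters the features;
horizontal displacement is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InvalidArgumentError,
    InvalidStateError,
)
from .track import TrajectorySet

__all__ = [
    "KinematicProfile",
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_kinematic_profile",
    "head_size_normalizer",
    "extract_features",
    "convert_to_mm",
    "features_from_trajectories",
]

_ROIS = ("head", "eyebrow", "lips")

# Feature layout: indices 1-12 distance (4 per ROI), 13-24 time (4 per
# ROI), 25-33 kinematics (3 per ROI); ROI order head, eyebrow, lips.
_DIST_STATS = ("max_raise", "max_lower", "mean_abs", "path_length")
_TIME_STATS = ("t_max_raise", "t_max_lower", "t_max_vel_raise", "t_max_vel_lower")
_KIN_STATS = ("max_vel_raise", "max_vel_lower", "max_abs_accel")

def _build_names() -> tuple[str, ...]:
    names = []
    idx = 1
    for block in (_DIST_STATS, _TIME_STATS, _KIN_STATS):
        for roi in _ROIS:
            for stat in block:
                names.append(f"f{idx:02d}_{roi}_{stat}")
                idx += 1
    return tuple(names)


FEATURE_NAMES = _build_names()
assert len(FEATURE_NAMES) == 33


@dataclass
class KinematicProfile:
    """Displacement/velocity/acceleration profile of one ROI.

    ``displacement`` has one entry per frame with d(0) = 0; velocity and
    acceleration are successive finite differences (one and two entries
    shorter) scaled to per-second units.
    """

    displacement: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    fps: float


@dataclass
class FeatureVector:
    """The 33 named features of one token plus their normalizer.

    ``units`` is ``"normalized"`` (head-size units) or ``"mm"`` after
    physical conversion.
    """

    values: np.ndarray
    normalizer: float
    units: str = "normalized"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (33,):
            raise InvalidArgumentError("a feature vector has exactly 33 values")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("feature values must be finite")

    def __getitem__(self, index: int) -> float:
        """1-based feature lookup matching the published feature table."""
        if not 1 <= index <= 33:
            raise InvalidArgumentError("feature index must be in 1..33")
        return float(self.values[index - 1])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values.tolist()))


def compute_kinematic_profile(track: np.ndarray, fps: float,
                              signal: str = "height") -> KinematicProfile:
    """Build a displacement/velocity/acceleration profile from a track.

    ``track`` is either a (T,) vertical signal or a (T, 2) position
    track whose y column is used.  With ``signal="height"`` the profile
    is d(t) = y(0) - y(t) (raising positive); with ``signal="aperture"``
    the input is already an aperture signal and d(t) = g(t) - g(0)
    (opening positive).
    """
    arr = np.asarray(track, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, 1]
    if arr.ndim != 1:
        raise InvalidArgumentError("track must be (T,) or (T, 2)")
    if len(arr) < 3:
        raise InvalidArgumentError("a profile needs at least 3 frames")
    if fps <= 0:
        raise InvalidArgumentError("fps must be > 0")
    if signal == "height":
        d = arr[0] - arr
    elif signal == "aperture":
        d = arr - arr[0]
    else:
        raise InvalidArgumentError(f"unknown signal kind {signal!r}")
    v = np.diff(d) * fps
    a = np.diff(d, n=2) * fps * fps
    return KinematicProfile(displacement=d, velocity=v, acceleration=a, fps=fps)


def head_size_normalizer(eye_left, eye_right, nose_tip) -> float:
    """Perpendicular distance (px) from the nose tip to the inter-eye line.

    This is the per-speaker scale factor dividing all distance and
    kinematic features.
    """
    e1 = np.asarray(eye_left, dtype=float)
    e2 = np.asarray(eye_right, dtype=float)
    n = np.asarray(nose_tip, dtype=float)
    line = e2 - e1
    norm = np.hypot(*line)
    if norm == 0:
        raise InvalidArgumentError("eye centers coincide")
    dist = abs(line[0] * (n[1] - e1[1]) - line[1] * (n[0] - e1[0])) / norm
    if dist == 0:
        raise DegenerateGeometryError("nose tip lies on the inter-eye line")
    return float(dist)


def _roi_features(profile: KinematicProfile, normalizer: float) -> list[float]:
    """The 11 per-ROI statistics, in (distance, time, kinematics) order."""
    d = profile.displacement / normalizer
    v = profile.velocity / normalizer
    a = profile.acceleration / normalizer
    T = len(d)
    denom = T - 1

    has_pos = np.any(d > 0)
    has_neg = np.any(d < 0)
    max_raise = float(d.max()) if has_pos else 0.0
    max_lower = float(-d.min()) if has_neg else 0.0
    mean_abs = float(np.abs(d).mean())
    path = float(np.abs(np.diff(d)).sum())

    t_max_raise = float(np.argmax(d)) / denom if has_pos else 0.0
    t_max_lower = float(np.argmin(d)) / denom if has_neg else 0.0

    pos_v = v > 0
    neg_v = v < 0
    if pos_v.any():
        vi = int(np.flatnonzero(pos_v)[np.argmax(v[pos_v])])
        max_vel_raise = float(v[vi])
        t_max_vel_raise = vi / denom
    else:
        max_vel_raise = 0.0
        t_max_vel_raise = 0.0
    if neg_v.any():
        vi = int(np.flatnonzero(neg_v)[np.argmin(v[neg_v])])
        max_vel_lower = float(-v[vi])
        t_max_vel_lower = vi / denom
    else:
        max_vel_lower = 0.0
        t_max_vel_lower = 0.0

    max_abs_accel = float(np.abs(a).max()) if len(a) else 0.0

    return [max_raise, max_lower, mean_abs, path,
            t_max_raise, t_max_lower, t_max_vel_raise, t_max_vel_lower,
            max_vel_raise, max_vel_lower, max_abs_accel]


def extract_features(head: KinematicProfile, eyebrow: KinematicProfile,
                     lips: KinematicProfile, normalizer: float) -> FeatureVector:
    """Summarize the three ROI profiles into the 33-feature vector.

    Per ROI: maximum raising (or opening) displacement, maximum lowering
    (closing) displacement, mean absolute displacement, path length;
    relative times (index / (T-1)) of the displacement extrema and of
    the velocity extremum within the rising (v > 0) and falling (v < 0)
    phases; maximum rising velocity, maximum falling speed, and maximum
    absolute acceleration.  A profile with no positive (or negative)
    excursion contributes 0 for that magnitude and for its relative
    time.  Extremum ties resolve to the earliest frame.
    """
    if normalizer <= 0:
        raise InvalidArgumentError("normalizer must be > 0")
    profiles = {"head": head, "eyebrow": eyebrow, "lips": lips}
    lengths = {len(p.displacement) for p in profiles.values()}
    if len(lengths) != 1:
        raise InvalidArgumentError("profiles must cover the same frame count")
    per_roi = {roi: _roi_features(p, normalizer) for roi, p in profiles.items()}
    values = []
    for block in (slice(0, 4), slice(4, 8), slice(8, 11)):
        for roi in _ROIS:
            values.extend(per_roi[roi][block])
    return FeatureVector(values=np.array(values), normalizer=float(normalizer),
                         units="normalized")


# index ranges of the dimensionless time features (1-based 13..24)
_TIME_SLICE = slice(12, 24)


def convert_to_mm(features: FeatureVector, head_size_mm: float) -> FeatureVector:
    """Convert a normalized feature vector to physical units.

    Distances become mm, velocities mm/s, accelerations mm/s^2; the
    dimensionless relative-time features are untouched.  Converting an
    already-converted vector raises.
    """
    if features.units != "normalized":
        raise InvalidStateError("features are already in physical units")
    if head_size_mm <= 0:
        raise InvalidArgumentError("head_size_mm must be > 0")
    values = features.values * head_size_mm
    values[_TIME_SLICE] = features.values[_TIME_SLICE]
    return replace(features, values=values, units="mm")


def features_from_trajectories(trajectories: TrajectorySet,
                               normalizer: float) -> FeatureVector:
    """Convenience: compensated trajectories -> 33-feature vector.

    Head features come from the nose track, eyebrow features from the
    eyebrow track, and lip features from the aperture signal
    y_lower - y_upper.
    """
    if not trajectories.compensated:
        raise InvalidStateError(
            "remove_head_translation must run before feature extraction")
    fps = trajectories.fps
    head = compute_kinematic_profile(trajectories.positions["nose"], fps)
    eyebrow = compute_kinematic_profile(trajectories.positions["eyebrow"], fps)
    aperture = (trajectories.positions["lower_lip"][:, 1]
                - trajectories.positions["upper_lip"][:, 1])
    lips = compute_kinematic_profile(aperture, fps, signal="aperture")
    return extract_features(head, eyebrow, lips, normalizer)


def features_to_frame(rows: list[tuple[int, FeatureVector]]) -> pd.DataFrame:
    """Feature vectors -> one-row-per-token DataFrame with named columns."""
    records = []
    for token_id, fv in rows:
        rec = {"token_id": token_id}
        rec.update(fv.to_dict())
        rec["normalizer_px"] = fv.normalizer
        rec["units"] = fv.units
        records.append(rec)
    cols = ["token_id", *FEATURE_NAMES, "normalizer_px", "units"]
    return pd.DataFrame(records, columns=cols)
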