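"""Ground-truthed synthetic fixtures.

Every pipeline stage is testable without recorded data through four
generators:

* :func:`render_face_video` draws a schematic frontal speaker — a
  skin-tone ellipse with shaded nose, dark eyebrow bars, eyes and
  crimson lips — animated by scripted head-translation, eyebrow and
  lip-aperture waveforms, and emits the analytic keypoint tracks and
  contours alongside the pixels.  Shapes are anti-aliased and the skin
  carries a faint luminance texture that moves with the head, so
  gradient-based tracking is well conditioned.  Schematic faces carry
  the color/intensity structure the refinement stages (HSV lip masks,
  eyebrow evidence fusion, active contours, KLT) actually consume;
  what they do not emulate is photographic appearance, so cascade-style
  appearance detectors are exercised through the pluggable detector
  interface instead.
* :func:`synth_token_audio` produces bursts of band-limited noise over
  a known noise floor with exact burst intervals.
* :func:`synth_trajectory` produces analytic keypoint trajectories
  together with feature values computed by an independent plain-loop
  reference, for oracle comparison against the vectorized extractor.
* :func:`synth_feature_table` produces labeled Gaussian feature tables
  with planted informative dimensions of known effect size.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .audio import AudioTrack
from .errors import InvalidArgumentError
from .features import FEATURE_NAMES, FeatureVector
from .significance import LabeledFeatureTable

__all__ = [
    "FaceSceneSpec",
    "FaceVideo",
    "FeatureTableSpec",
    "render_face_video",
    "synth_token_audio",
    "synth_trajectory",
    "synth_feature_table",
]

# Palette chosen so the HSV rules of detect.GeometryDetector separate the
# parts crisply: skin-tone face, darker-shaded nose, near-white sclera,
# crimson lips, dark mouth interior, cool dark background.
DEFAULT_COLORS = {
    "background": (70, 80, 95),
    "skin": (230, 180, 140),
    "nose": (205, 145, 100),
    "eyebrow": (60, 40, 30),
    "sclera": (245, 245, 245),
    "pupil": (30, 30, 30),
    "lip": (200, 30, 90),
    "mouth": (60, 15, 25),
}


@dataclass
class FaceSceneSpec:
    """Layout and motion script of one rendered talking-face video.

    Motion waveforms are per-frame pixel offsets: ``head_x``/``head_y``
    translate the whole face, ``brow_dy`` moves the eyebrows relative to
    the head (negative = raise, image y grows downward) and
    ``aperture`` opens the lips (inner-edge separation, >= 0).  Omitted
    waveforms default to zero (a resting face).
    """

    height: int = 270
    width: int = 480
    fps: float = 29.97
    n_frames: int = 30
    head_x: np.ndarray | None = None
    head_y: np.ndarray | None = None
    brow_dy: np.ndarray | None = None
    aperture: np.ndarray | None = None
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    texture_amplitude: float = 0.03
    seed: int = 0

    def __post_init__(self):
        for name in ("head_x", "head_y", "brow_dy", "aperture"):
            wave = getattr(self, name)
            if wave is None:
                wave = np.zeros(self.n_frames)
            wave = np.asarray(wave, dtype=float)
            if wave.shape != (self.n_frames,):
                raise InvalidArgumentError(
                    f"waveform {name} must have one value per frame")
            setattr(self, name, wave)
        if np.any(self.aperture < 0):
            raise InvalidArgumentError("lip aperture must be non-negative")

    # -- derived layout (pixels) ------------------------------------------
    @property
    def face_center(self) -> tuple[float, float]:
        return self.width / 2.0, self.height * 0.50

    @property
    def face_axes(self) -> tuple[float, float]:
        return 0.11 * self.width, 0.30 * self.height

    def layout(self) -> dict:
        cx, cy = self.face_center
        a, b = self.face_axes
        r_eye = 0.15 * a
        return {
            "eye_dx": 0.45 * a, "eye_y": cy - 0.35 * b, "r_eye": r_eye,
            "r_pupil": 0.06 * a,
            "brow_cy": cy - 0.56 * b, "brow_hw": 0.28 * a, "brow_hh": 0.05 * b,
            "nose_cy": cy + 0.05 * b, "nose_a": 0.32 * a, "nose_b": 0.085 * b,
            "lip_cy": cy + 0.60 * b, "lip_a": 0.38 * a, "lip_hh": 0.05 * b,
            "mouth_a": 0.30 * a,
        }

    def validate(self) -> None:
        cx, cy = self.face_center
        a, b = self.face_axes
        margin = 2.0
        if (cx - a + self.head_x.min() < margin
                or cx + a + self.head_x.max() > self.width - margin
                or cy - b + self.head_y.min() < margin
                or cy + b + self.head_y.max() > self.height - margin):
            raise InvalidArgumentError("face leaves the frame under this motion")

    @classmethod
    def scripted(cls, height: int = 270, width: int = 480, fps: float = 29.97,
                 n_frames: int = 64, head_amp: float | None = None,
                 brow_amp: float | None = None, aperture_amp: float | None = None,
                 seed: int = 0) -> "FaceSceneSpec":
        """A standard speech-like motion script scaled to the frame.

        Defaults emulate one monosyllabic utterance: a gentle head sway
        (~1% of frame height), one eyebrow raise (~2.3%) and one
        open-close lip cycle (~3.7%), all starting from rest at frame 0.
        """
        head_amp = 0.011 * height if head_amp is None else head_amp
        brow_amp = 0.023 * height if brow_amp is None else brow_amp
        aperture_amp = 0.037 * height if aperture_amp is None else aperture_amp
        t = np.arange(n_frames) / max(1, n_frames - 1)
        bump_brow = np.sin(np.pi * np.clip((t - 0.10) / 0.50, 0, 1)) ** 2
        bump_lips = np.sin(np.pi * np.clip((t - 0.20) / 0.60, 0, 1)) ** 2
        spec = cls(
            height=height, width=width, fps=fps, n_frames=n_frames,
            head_x=0.6 * head_amp * np.sin(np.pi * t),
            head_y=head_amp * np.sin(2 * np.pi * t),
            brow_dy=-brow_amp * bump_brow,
            aperture=aperture_amp * bump_lips,
            seed=seed,
        )
        spec.validate()
        return spec


def _blend(img: np.ndarray, color, alpha: np.ndarray, ys: slice, xs: slice) -> None:
    """Alpha-composite a color (scalar RGB or per-pixel field) onto a
    bounding-box slice of the image."""
    region = img[ys, xs]
    a = alpha[..., None]
    img[ys, xs] = region * (1 - a) + np.asarray(color, dtype=float) * a


def _bbox(cx, cy, rx, ry, h, w, pad=2.0):
    x0 = max(0, int(np.floor(cx - rx - pad)))
    x1 = min(w, int(np.ceil(cx + rx + pad)) + 1)
    y0 = max(0, int(np.floor(cy - ry - pad)))
    y1 = min(h, int(np.ceil(cy + ry + pad)) + 1)
    return slice(y0, y1), slice(x0, x1)


def _grid(ys: slice, xs: slice):
    yy = np.arange(ys.start, ys.stop, dtype=float)[:, None]
    xx = np.arange(xs.start, xs.stop, dtype=float)[None, :]
    return yy, xx


def _ellipse_alpha(yy, xx, cx, cy, a, b):
    f = np.sqrt(((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2)
    d = (f - 1.0) * min(a, b)  # approximate signed distance to the boundary
    return np.clip(0.5 - d, 0.0, 1.0)


def _rect_alpha(yy, xx, cx, cy, hw, hh):
    d = np.maximum(np.abs(xx - cx) - hw, np.abs(yy - cy) - hh)
    return np.clip(0.5 - d, 0.0, 1.0)


class FaceVideo:
    """A lazily rendered schematic face video plus its ground truth.

    Frames are rendered on demand (``video[i]``, ``len(video)``) so
    full-HD sequences never need to sit in memory at once.  Ground truth
    comes from the same analytic layout that drives the renderer:
    ``keypoint_tracks`` are the four keypoints per frame,
    ``contours(i)`` are the per-frame reference curves and
    ``lip_mask(i)`` is the filled outer-lip region.
    """

    def __init__(self, spec: FaceSceneSpec):
        spec.validate()
        self.spec = spec
        self._layout = spec.layout()

    def __len__(self) -> int:
        return self.spec.n_frames

    @property
    def fps(self) -> float:
        return self.spec.fps

    def _frame_params(self, i: int) -> dict:
        s = self.spec
        L = self._layout
        hx, hy = s.head_x[i], s.head_y[i]
        cx, cy = s.face_center
        ap = s.aperture[i]
        return {
            "hx": hx, "hy": hy,
            "cx": cx + hx, "cy": cy + hy,
            "brow_cy": L["brow_cy"] + s.brow_dy[i] + hy,
            "lip_b_out": L["lip_hh"] + ap / 2.0,
            "lip_b_in": ap / 2.0,
        }

    def __getitem__(self, i: int) -> np.ndarray:
        if i < 0:
            i += len(self)
        if not 0 <= i < len(self):
            raise IndexError(i)
        s = self.spec
        L = self._layout
        P = self._frame_params(i)
        h, w = s.height, s.width
        colors = s.colors
        img = np.empty((h, w, 3), dtype=float)
        img[:] = np.asarray(colors["background"], dtype=float)

        a, b = s.face_axes
        cx, cy = P["cx"], P["cy"]

        def textured(base, yy, xx):
            tex = 1.0 + s.texture_amplitude * (
                np.sin(2 * np.pi * (xx - P["hx"]) / 21.0)
                * np.sin(2 * np.pi * (yy - P["hy"]) / 17.0))
            return np.asarray(base, dtype=float) * tex[..., None]

        # face ellipse (textured skin)
        ys, xs = _bbox(cx, cy, a, b, h, w)
        yy, xx = _grid(ys, xs)
        alpha = _ellipse_alpha(yy, xx, cx, cy, a, b)
        _blend(img, textured(colors["skin"], yy, xx), alpha, ys, xs)

        # nose: lower half-ellipse of darker skin
        nose_cy = L["nose_cy"] + P["hy"]
        ys, xs = _bbox(cx, nose_cy, L["nose_a"], L["nose_b"], h, w)
        yy, xx = _grid(ys, xs)
        alpha = _ellipse_alpha(yy, xx, cx, nose_cy, L["nose_a"], L["nose_b"])
        alpha *= np.clip(yy - nose_cy + 0.5, 0.0, 1.0)  # keep the lower half
        _blend(img, textured(colors["nose"], yy, xx), alpha, ys, xs)

        # eyebrows, eyes
        for side in (-1, 1):
            ex = cx + side * L["eye_dx"]
            ys, xs = _bbox(ex, P["brow_cy"], L["brow_hw"], L["brow_hh"], h, w)
            yy, xx = _grid(ys, xs)
            alpha = _rect_alpha(yy, xx, ex, P["brow_cy"], L["brow_hw"], L["brow_hh"])
            _blend(img, colors["eyebrow"], alpha, ys, xs)

            ey = L["eye_y"] + P["hy"]
            ys, xs = _bbox(ex, ey, L["r_eye"], L["r_eye"], h, w)
            yy, xx = _grid(ys, xs)
            alpha = _ellipse_alpha(yy, xx, ex, ey, L["r_eye"], L["r_eye"])
            _blend(img, colors["sclera"], alpha, ys, xs)
            ys, xs = _bbox(ex, ey, L["r_pupil"], L["r_pupil"], h, w)
            yy, xx = _grid(ys, xs)
            alpha = _ellipse_alpha(yy, xx, ex, ey, L["r_pupil"], L["r_pupil"])
            _blend(img, colors["pupil"], alpha, ys, xs)

        # lips: outer crimson ellipse, dark interior when open
        lip_cy = L["lip_cy"] + P["hy"]
        ys, xs = _bbox(cx, lip_cy, L["lip_a"], P["lip_b_out"], h, w)
        yy, xx = _grid(ys, xs)
        alpha = _ellipse_alpha(yy, xx, cx, lip_cy, L["lip_a"], P["lip_b_out"])
        _blend(img, colors["lip"], alpha, ys, xs)
        if P["lip_b_in"] >= 0.3:
            ys, xs = _bbox(cx, lip_cy, L["mouth_a"], P["lip_b_in"], h, w)
            yy, xx = _grid(ys, xs)
            alpha = _ellipse_alpha(yy, xx, cx, lip_cy, L["mouth_a"], P["lip_b_in"])
            _blend(img, colors["mouth"], alpha, ys, xs)

        return np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # -- ground truth ------------------------------------------------------
    @property
    def keypoint_tracks(self) -> dict[str, np.ndarray]:
        """Analytic per-frame positions of the four tracked keypoints."""
        s = self.spec
        L = self._layout
        cx, cy0 = s.face_center
        T = s.n_frames
        out = {k: np.empty((T, 2)) for k in
               ("nose", "eyebrow", "upper_lip", "lower_lip")}
        for i in range(T):
            P = self._frame_params(i)
            # detected nose tip = mean of the lower-edge arc; for a
            # half-ellipse sampled per column the mean depth is (pi/4) b
            out["nose"][i] = (P["cx"], L["nose_cy"] + P["hy"]
                              + (np.pi / 4) * L["nose_b"])
            out["eyebrow"][i] = (P["cx"] - L["eye_dx"],
                                 P["brow_cy"] - L["brow_hh"])
            lip_cy = L["lip_cy"] + P["hy"]
            out["upper_lip"][i] = (P["cx"], lip_cy - P["lip_b_out"])
            out["lower_lip"][i] = (P["cx"], lip_cy + P["lip_b_out"])
        return out

    def eye_centers(self, i: int = 0) -> tuple[tuple[float, float], tuple[float, float]]:
        P = self._frame_params(i)
        L = self._layout
        ey = L["eye_y"] + P["hy"]
        return ((P["cx"] - L["eye_dx"], ey), (P["cx"] + L["eye_dx"], ey))

    def contours(self, i: int) -> dict[str, np.ndarray]:
        """Reference curves at frame i: nose lower edge, eyebrow ridge,
        outer upper/lower lip, sampled at ~1 px spacing."""
        L = self._layout
        P = self._frame_params(i)

        def arc(cx, cy, a, b, sign):
            xs = np.linspace(cx - a, cx + a, max(16, int(4 * a)))  # ~0.5 px
            u = np.clip((xs - cx) / a, -1, 1)
            return np.column_stack([xs, cy + sign * b * np.sqrt(1 - u ** 2)])

        nose_cy = L["nose_cy"] + P["hy"]
        lip_cy = L["lip_cy"] + P["hy"]
        brow_top = P["brow_cy"] - L["brow_hh"]
        bx = P["cx"] - L["eye_dx"]
        brow_xs = np.linspace(bx - L["brow_hw"], bx + L["brow_hw"],
                              max(8, int(2 * L["brow_hw"])))
        return {
            "nose": arc(P["cx"], nose_cy, L["nose_a"], L["nose_b"], +1),
            "eyebrow": np.column_stack([brow_xs, np.full_like(brow_xs, brow_top)]),
            "upper_lip": arc(P["cx"], lip_cy, L["lip_a"], P["lip_b_out"], -1),
            "lower_lip": arc(P["cx"], lip_cy, L["lip_a"], P["lip_b_out"], +1),
        }

    def lip_mask(self, i: int = 0) -> np.ndarray:
        """Filled outer-lip region (boolean, full frame) at frame i."""
        s = self.spec
        L = self._layout
        P = self._frame_params(i)
        yy = np.arange(s.height, dtype=float)[:, None]
        xx = np.arange(s.width, dtype=float)[None, :]
        lip_cy = L["lip_cy"] + P["hy"]
        f = (((xx - P["cx"]) / L["lip_a"]) ** 2
             + ((yy - lip_cy) / P["lip_b_out"]) ** 2)
        return f <= 1.0


def render_face_video(spec: FaceSceneSpec) -> FaceVideo:
    """Render a schematic talking face; see :class:`FaceVideo`."""
    return FaceVideo(spec)


def synth_token_audio(n_tokens: int, token_length_s: float = 0.8,
                      gap_s: float = 1.0, rate: float = 16000.0,
                      peak: float = 1.0, noise_floor: float = 0.01,
                      seed: int = 0) -> tuple[AudioTrack, list[tuple[int, int]]]:
    """Token bursts of band-limited noise over a silent noise floor.

    The layout is gap, token, gap, token, ..., gap; each burst is
    normalized to the requested peak amplitude and its exact sample
    interval [start, end) is returned as ground truth.
    """
    if peak <= noise_floor or noise_floor < 0:
        raise InvalidArgumentError("need peak > noise_floor >= 0")
    if n_tokens < 0:
        raise InvalidArgumentError("n_tokens must be >= 0")
    if token_length_s <= 0 or gap_s <= 0:
        raise InvalidArgumentError(
            "token and gap lengths must be positive (bursts may not overlap)")
    rng = np.random.default_rng(seed)
    tok = int(round(token_length_s * rate))
    gap = int(round(gap_s * rate))
    total = gap + n_tokens * (tok + gap)
    samples = rng.uniform(-1.0, 1.0, total)
    if noise_floor > 0:
        samples *= noise_floor / np.abs(samples).max()
    else:
        samples[:] = 0.0
    b, a = butter(4, 0.5)
    intervals = []
    for i in range(n_tokens):
        start = gap + i * (tok + gap)
        burst = filtfilt(b, a, rng.uniform(-1.0, 1.0, tok))
        burst *= peak / np.abs(burst).max()
        samples[start:start + tok] = burst
        intervals.append((start, start + tok))
    return AudioTrack(samples=samples, rate=rate), intervals


def _reference_roi_stats(d, fps: float, normalizer: float) -> list[float]:
    """Plain-loop reference for the 11 per-ROI statistics.

    Deliberately elementary (explicit loops, no shared code with the
    extractor) so it can serve as an independent oracle.  ``d`` is the
    per-frame displacement signal (d[0] = 0).  Differences are taken on
    the raw displacement and the head-size normalization applied to the
    resulting statistics; scaling by a positive constant commutes with
    every extremum, so the definition is unchanged, while extremum ties
    on analytically flat segments (e.g. the constant velocity of a
    triangle ramp) resolve on the very same float sequence the
    extractor sees.
    """
    T = len(d)
    v = [(d[i + 1] - d[i]) * fps for i in range(T - 1)]
    a = [((d[i + 2] - d[i + 1]) - (d[i + 1] - d[i])) * fps * fps
         for i in range(T - 2)]
    d = [x / normalizer for x in d]
    v = [x / normalizer for x in v]
    a = [x / normalizer for x in a]

    max_raise = 0.0
    t_raise = 0
    max_lower = 0.0
    t_lower = 0
    for i, x in enumerate(d):
        if x > max_raise:
            max_raise, t_raise = x, i
        if -x > max_lower:
            max_lower, t_lower = -x, i
    mean_abs = sum(abs(x) for x in d) / T
    path = sum(abs(d[i + 1] - d[i]) for i in range(T - 1))

    mv_raise = 0.0
    ti_raise = 0
    mv_lower = 0.0
    ti_lower = 0
    for i, x in enumerate(v):
        if x > 0 and x > mv_raise:
            mv_raise, ti_raise = x, i
        if x < 0 and -x > mv_lower:
            mv_lower, ti_lower = -x, i
    max_acc = max((abs(x) for x in a), default=0.0)

    denom = T - 1
    return [max_raise, max_lower, mean_abs, path,
            t_raise / denom if max_raise > 0 else 0.0,
            t_lower / denom if max_lower > 0 else 0.0,
            ti_raise / denom if mv_raise > 0 else 0.0,
            ti_lower / denom if mv_lower > 0 else 0.0,
            mv_raise, mv_lower, max_acc]


def synth_trajectory(kind: str, frames: int, fps: float = 29.97,
                     amplitude: float = 10.0, trough: float = 5.0,
                     peak_time: float = 0.3, trough_time: float = 0.8,
                     period: float | None = None, y0: float = 100.0,
                     normalizer: float = 1.0,
                     ) -> tuple[np.ndarray, FeatureVector]:
    """An analytic vertical trajectory and its reference feature values.

    ``kind`` is ``"triangle"`` (rise linearly to +amplitude at
    peak_time, fall to -trough at trough_time, return to rest) or
    ``"sinusoid"`` (displacement amplitude*sin(2 pi t / period)).
    Returns the y-position track y(t) = y0 - d(t) and the feature
    vector computed by the plain-loop reference with the same profile
    assigned to all three regions of interest, so each ROI block holds
    identical values for oracle comparison.
    """
    if frames < 3:
        raise InvalidArgumentError("need at least 3 frames")
    t = np.arange(frames, dtype=float)
    if kind == "triangle":
        p = peak_time * (frames - 1)
        q = trough_time * (frames - 1)
        if not 0 < p < q < frames - 1 + 1e-9:
            raise InvalidArgumentError("need 0 < peak_time < trough_time <= 1")
        d = np.empty(frames)
        for i in range(frames):
            if t[i] <= p:
                d[i] = amplitude * t[i] / p
            elif t[i] <= q:
                d[i] = amplitude - (amplitude + trough) * (t[i] - p) / (q - p)
            else:
                d[i] = -trough + trough * (t[i] - q) / (frames - 1 - q) \
                    if frames - 1 > q else -trough
    elif kind == "sinusoid":
        if period is None or period <= 0:
            raise InvalidArgumentError("sinusoid needs a positive period")
        d = amplitude * np.sin(2 * np.pi * t / period)
    else:
        raise InvalidArgumentError(f"unknown trajectory kind {kind!r}")

    # the oracle sees the displacement exactly as a consumer of the
    # returned y-track would reconstruct it: d(t) = y(0) - y(t)
    y = y0 - d
    stats = _reference_roi_stats([float(y[0]) - float(y[i]) for i in range(frames)],
                                 fps, normalizer)
    values = []
    for block in (slice(0, 4), slice(4, 8), slice(8, 11)):
        for _roi in range(3):
            values.extend(stats[block])
    fv = FeatureVector(values=np.array(values), normalizer=normalizer)
    return y, fv


@dataclass
class FeatureTableSpec:
    """Spec for a labeled feature table with planted structure.

    ``informative`` maps a class label to the 1-based feature indices
    shifted by ``effect_size`` noise-SD units in that class.
    """

    n_classes: int = 4
    n_per_class: int = 100
    informative: dict = field(default_factory=dict)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2 or self.n_per_class < 2:
            raise InvalidArgumentError("need >= 2 classes with >= 2 rows each")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise InvalidArgumentError("effect >= 0 and noise SD > 0 required")
        for cls, indices in self.informative.items():
            if not 1 <= cls <= self.n_classes:
                raise InvalidArgumentError(f"unknown class {cls!r}")
            for j in indices:
                if not 1 <= j <= 33:
                    raise InvalidArgumentError("feature indices are 1..33")


def synth_feature_table(spec: FeatureTableSpec) -> LabeledFeatureTable:
    """Gaussian 33-feature table with planted class shifts.

    Noise features are i.i.d. N(0, sd); each informative feature's mean
    is shifted by effect_size * sd in its designated class only.
    Deterministic given the spec's seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.n_per_class
    X = rng.normal(0.0, spec.noise_sd, size=(n, 33))
    y = np.repeat(np.arange(1, spec.n_classes + 1), spec.n_per_class)
    for cls, indices in spec.informative.items():
        rows = y == cls
        for j in indices:
            X[rows, j - 1] += spec.effect_size * spec.noise_sd
    return LabeledFeatureTable(X=X, y=y, feature_names=list(FEATURE_NAMES))
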