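"""Pipeline configuration.

All defaults reproduce the reference parameterization of the method
(audio threshold at 20% of maximum, median filter of order 5, noise
clusters below 35% of the longest cluster, merge-threshold schedules per
detector, 500/400-iteration active contours, 500-tree forests with
minimum leaf size 20, r = 500 balanced-bootstrap draws repeated N = 300
times, BH significance at alpha = 0.05).  Configs are plain dataclasses
serializable to YAML/JSON; unknown keys are rejected on load so typos
never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import InvalidArgumentError

__all__ = [
    "SegmenterConfig",
    "ThresholdSchedule",
    "DetectorConfig",
    "TrackerConfig",
    "FeatureConfig",
    "RFConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class SegmenterConfig:
    """Audio-driven token segmentation parameters."""

    threshold_fraction: float = 0.20   # fraction of max filtered energy
    energy_window: int = 400           # samples; 25 ms at 16 kHz
    energy_step: int = 1               # samples
    median_order: int = 5              # odd
    min_cluster_fraction: float = 0.35  # of the longest cluster
    buffer_frames: int = 10            # video frames padded on each side
    video_fps: float = 29.97
    enabled: bool = True               # skip when input is pre-tokenized

    def validate(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise InvalidArgumentError("threshold_fraction must be in (0, 1)")
        if self.median_order % 2 == 0 or self.median_order < 1:
            raise InvalidArgumentError("median_order must be odd and >= 1")
        if self.buffer_frames < 0:
            raise InvalidArgumentError("buffer_frames must be >= 0")
        if self.energy_window < 1 or self.energy_step < 1:
            raise InvalidArgumentError("energy window/step must be >= 1")
        if not 0 < self.min_cluster_fraction < 1:
            raise InvalidArgumentError("min_cluster_fraction must be in (0, 1)")
        if self.video_fps <= 0:
            raise InvalidArgumentError("video_fps must be > 0")


@dataclass
class ThresholdSchedule:
    """Merge-threshold sweep for one detector kind: start..stop by step.

    ``adaptive`` halves the step (floor 1) whenever the number of raw
    detections fails to decrease between consecutive thresholds.
    """

    start: int = 1
    stop: int = 150
    step: int = 10
    adaptive: bool = False

    def validate(self) -> None:
        if self.start > self.stop:
            raise InvalidArgumentError("schedule start must be <= stop")
        if self.step <= 0:
            raise InvalidArgumentError("schedule step must be > 0")


def _sched(start: int, stop: int = 150, step: int = 10, adaptive: bool = False) -> ThresholdSchedule:
    return ThresholdSchedule(start=start, stop=stop, step=step, adaptive=adaptive)


@dataclass
class DetectorConfig:
    """Region-of-interest detection and refinement parameters."""

    face_schedule: ThresholdSchedule = field(default_factory=lambda: _sched(1))
    eye_pair_schedule: ThresholdSchedule = field(default_factory=lambda: _sched(0, adaptive=True))
    left_eye_schedule: ThresholdSchedule = field(default_factory=lambda: _sched(4))
    nose_schedule: ThresholdSchedule = field(default_factory=lambda: _sched(1))
    mouth_schedule: ThresholdSchedule = field(default_factory=lambda: _sched(4))
    nose_ac_iters: int = 500
    nose_ac_smoothness: int = 2
    eyebrow_ac_iters: int = 400
    lip_ac_iters: int = 500
    lip_ac_smoothness: int = 2
    lip_on_fraction: float = 0.48      # H/S "ON" rule for mask intersection
    lip_dilate_radius: int = 7         # disk structuring element
    eyebrow_patch_fraction: float = 0.10  # P as fraction of eye-box height
    eyebrow_shift_fraction: float = 0.60  # eye box -> eyebrow box upward shift

    def validate(self) -> None:
        for name in ("face", "eye_pair", "left_eye", "nose", "mouth"):
            getattr(self, f"{name}_schedule").validate()
        for frac in (self.lip_on_fraction, self.eyebrow_patch_fraction,
                     self.eyebrow_shift_fraction):
            if not 0 < frac < 1:
                raise InvalidArgumentError("detector fractions must be in (0, 1)")
        for n in (self.nose_ac_iters, self.eyebrow_ac_iters, self.lip_ac_iters,
                  self.lip_dilate_radius):
            if n < 1:
                raise InvalidArgumentError("iteration/radius counts must be >= 1")

    def schedule_for(self, kind: str) -> ThresholdSchedule:
        try:
            return getattr(self, f"{kind}_schedule")
        except AttributeError:
            raise InvalidArgumentError(f"unknown detector kind {kind!r}") from None


@dataclass
class TrackerConfig:
    """Pyramidal Lucas-Kanade point tracker settings."""

    pyramid_levels: int = 3
    window_size: int = 31          # odd; per-level integration window
    max_iterations: int = 30       # per level
    convergence_eps: float = 0.01  # px; stop when update is smaller
    smoothing_sigma: float = 1.0   # Gaussian presmoothing per level

    def validate(self) -> None:
        if self.pyramid_levels < 1:
            raise InvalidArgumentError("pyramid_levels must be >= 1")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise InvalidArgumentError("window_size must be odd and >= 3")
        if self.max_iterations < 1:
            raise InvalidArgumentError("max_iterations must be >= 1")


@dataclass
class FeatureConfig:
    """Feature extraction settings."""

    head_size_mm: float | None = None   # physical head size; None = stay normalized

    def validate(self) -> None:
        if self.head_size_mm is not None and self.head_size_mm <= 0:
            raise InvalidArgumentError("head_size_mm must be > 0")


@dataclass
class RFConfig:
    """Balanced-bootstrap one-vs-all random-forest significance settings."""

    n_trees: int = 500
    min_leaf: int = 20
    r: int = 500                      # balanced samples drawn per class
    n_bootstrap: int = 300            # N: bootstrap repeats per OVA problem
    train_fraction: float = 0.90
    importance_iterations: int = 50
    permutation_repeats: int = 50
    alpha: float = 0.05
    seed: int = 1

    def validate(self) -> None:
        for name in ("n_trees", "min_leaf", "r", "n_bootstrap",
                     "importance_iterations", "permutation_repeats"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise InvalidArgumentError("train_fraction must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (nested per-stage configs)."""

    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    seed: int = 1

    def validate(self) -> None:
        self.segmenter.validate()
        self.detector.validate()
        self.tracker.validate()
        self.features.validate()
        self.rf.validate()

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _build(cls, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise InvalidArgumentError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict) and key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value, f"{path}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "segmenter": SegmenterConfig,
    "detector": DetectorConfig,
    "tracker": TrackerConfig,
    "features": FeatureConfig,
    "rf": RFConfig,
    "face_schedule": ThresholdSchedule,
    "eye_pair_schedule": ThresholdSchedule,
    "left_eye_schedule": ThresholdSchedule,
    "nose_schedule": ThresholdSchedule,
    "mouth_schedule": ThresholdSchedule,
}


def config_from_dict(data: dict[str, Any] | None) -> PipelineConfig:
    """Build a validated PipelineConfig from a (possibly partial) mapping.

    Omitted keys take the reference defaults; unknown keys raise.
    """
    cfg = _build(PipelineConfig, data or {}, "config")
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file. An empty file yields all defaults."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InvalidArgumentError(f"could not parse {path}: {exc}") from exc
    return config_from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Serialize a config; load_config(save_config(c)) round-trips."""
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
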