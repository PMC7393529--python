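"""Audio-driven token segmentation.

A continuous recording of many single-word utterances is split into
per-token video segments using only the audio track: short-time energy
is computed over a sliding window, median-filtered, and thresholded at a
fraction (default 20%) of its global maximum.  Contiguous supra-threshold
runs ("clusters") correspond to utterances; short clusters (keystrokes,
coughs) are discarded as noise, and each surviving cluster is mapped to
video frames and padded with a fixed frame buffer (default 10 frames,
about 0.3 s at 29.97 fps).

Because the threshold is relative to the recording's own maximum, the
segmentation is invariant to overall gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import medfilt

from .config import SegmenterConfig
from .errors import InvalidArgumentError

__all__ = [
    "AudioTrack",
    "TokenSegment",
    "read_wav",
    "compute_short_time_energy",
    "map_sample_to_frame",
    "segment_tokens",
    "segments_to_frame",
    "write_segments_manifest",
]


@dataclass
class AudioTrack:
    """Mono audio samples in [-1, 1] plus the sample rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise InvalidArgumentError("audio rate must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class TokenSegment:
    """One utterance: video frame interval [start_frame, end_frame) plus
    the audio sample span the underlying energy cluster covered."""

    start_frame: int
    end_frame: int
    start_sample: int
    end_sample: int

    def __post_init__(self):
        if not (0 <= self.start_frame < self.end_frame):
            raise InvalidArgumentError(
                f"invalid frame interval [{self.start_frame}, {self.end_frame})")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def read_wav(path: str | Path) -> AudioTrack:
    """Read a PCM WAV file as a mono AudioTrack scaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return AudioTrack(samples=data.astype(float), rate=float(rate))


def compute_short_time_energy(audio: AudioTrack, window: int, step: int = 1) -> np.ndarray:
    """Short-time energy: sum of squared samples in a sliding window.

    ``energy[i]`` covers samples ``[i*step, i*step + window)``; the output
    has ``floor((n - window) / step) + 1`` entries.
    """
    if window < 1 or step < 1:
        raise InvalidArgumentError("window and step must be >= 1")
    n = len(audio.samples)
    if window > n:
        raise InvalidArgumentError(f"window ({window}) longer than signal ({n})")
    sq = np.square(audio.samples)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    starts = np.arange(0, n - window + 1, step)
    return csum[starts + window] - csum[starts]


def map_sample_to_frame(sample_index: int, audio_rate: float, fps: float) -> int:
    """Align the audio and video clocks: floor(sample / rate * fps)."""
    if sample_index < 0:
        raise InvalidArgumentError("sample_index must be >= 0")
    if audio_rate <= 0 or fps <= 0:
        raise InvalidArgumentError("rates must be > 0")
    return int(np.floor(sample_index / audio_rate * fps))


def _clusters(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous True runs as (first, last) inclusive index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def segment_tokens(audio: AudioTrack, config: SegmenterConfig | None = None,
                   n_frames: int | None = None) -> list[TokenSegment]:
    """Segment a recording into buffered per-token frame intervals.

    Median-filtered short-time energy is thresholded at
    ``threshold_fraction`` of its maximum; supra-threshold runs shorter
    than ``min_cluster_fraction`` of the longest run are dropped as
    noise; the rest are mapped to video frames, padded by
    ``buffer_frames`` on both sides (clipped to ``[0, n_frames)`` when
    the video length is known), and merged where buffers overlap.

    A recording with no supra-threshold samples (e.g. silence) returns
    an empty list.
    """
    config = config or SegmenterConfig()
    config.validate()
    if len(audio.samples) == 0:
        raise InvalidArgumentError("audio is empty")

    energy = compute_short_time_energy(audio, config.energy_window, config.energy_step)
    energy = medfilt(energy, kernel_size=config.median_order)
    peak = energy.max()
    if peak <= 0:
        return []
    mask = energy > config.threshold_fraction * peak
    if mask.mean() > 0.9:
        # the relative threshold separated nothing: a recording that is
        # supra-threshold almost everywhere (e.g. a uniform noise floor
        # with no utterances) has no token structure
        return []
    clusters = _clusters(mask)
    if not clusters:
        return []
    longest = max(last - first + 1 for first, last in clusters)
    clusters = [c for c in clusters
                if (c[1] - c[0] + 1) >= config.min_cluster_fraction * longest]

    step, window = config.energy_step, config.energy_window
    raw: list[TokenSegment] = []
    for first, last in clusters:
        start_sample = first * step
        end_sample = last * step + window            # audio extent of the cluster
        f0 = map_sample_to_frame(first * step, audio.rate, config.video_fps)
        f1 = map_sample_to_frame(last * step, audio.rate, config.video_fps)
        start = max(0, f0 - config.buffer_frames)
        end = f1 + config.buffer_frames + 1          # exclusive
        if n_frames is not None:
            end = min(end, n_frames)
            if start >= end:                         # cluster beyond the video
                continue
        raw.append(TokenSegment(start, end, start_sample, end_sample))

    # merge buffer-induced overlaps so no frame lands in two token files
    merged: list[TokenSegment] = []
    for seg in sorted(raw, key=lambda s: s.start_frame):
        if merged and seg.start_frame < merged[-1].end_frame:
            prev = merged[-1]
            merged[-1] = TokenSegment(prev.start_frame,
                                      max(prev.end_frame, seg.end_frame),
                                      prev.start_sample,
                                      max(prev.end_sample, seg.end_sample))
        else:
            merged.append(seg)
    return merged


def segments_to_frame(segments: list[TokenSegment]) -> pd.DataFrame:
    """Segments manifest as a DataFrame (token_id + frame/sample spans)."""
    return pd.DataFrame(
        [{"token_id": i, "start_frame": s.start_frame, "end_frame": s.end_frame,
          "start_sample": s.start_sample, "end_sample": s.end_sample}
         for i, s in enumerate(segments)],
        columns=["token_id", "start_frame", "end_frame", "start_sample", "end_sample"],
    )


def write_segments_manifest(segments: list[TokenSegment], path: str | Path) -> None:
    segments_to_frame(segments).to_csv(path, index=False)
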