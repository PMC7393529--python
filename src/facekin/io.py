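"""Reading and writing the pipeline's file formats.

Video comes in as numbered image sequences (PNG) or any in-memory
indexable frame sequence; audio as PCM WAV.  Stage outputs are plain
CSV/JSON so every intermediate is inspectable and joins on token_id.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detect import DetectionResult, KeypointSet
from .errors import InvalidArgumentError
from .track import KEYPOINT_NAMES, TrajectorySet

__all__ = [
    "read_image_sequence",
    "write_image_sequence",
    "write_keypoints_json",
    "read_keypoints_json",
    "trajectories_to_frame",
    "write_trajectories_csv",
    "read_trajectories_csv",
]


def read_image_sequence(path: str | Path) -> list[np.ndarray]:
    """Load a directory of numbered images (sorted by name) as frames."""
    path = Path(path)
    if not path.is_dir():
        raise InvalidArgumentError(f"{path} is not a directory")
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"})
    if not files:
        raise InvalidArgumentError(f"no image files in {path}")
    return [iio.imread(f)[..., :3] for f in files]


def write_image_sequence(frames, out_dir: str | Path, prefix: str = "frame") -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(len(frames)):
        p = out_dir / f"{prefix}_{i:05d}.png"
        iio.imwrite(p, np.asarray(frames[i]))
        paths.append(p)
    return paths


def write_keypoints_json(detection: DetectionResult, path: str | Path,
                         token_id: int = 0) -> None:
    kp = detection.keypoints
    data = {
        "token_id": token_id,
        "keypoints": {
            "nose": list(kp.nose_tip),
            "eyebrow": list(kp.eyebrow_mid),
            "upper_lip": list(kp.upper_lip),
            "lower_lip": list(kp.lower_lip),
        },
        "eye_centers": {"left": list(detection.eye_left),
                        "right": list(detection.eye_right)},
        "boxes": {name: {"x": b.x, "y": b.y, "w": b.w, "h": b.h}
                  for name, b in detection.boxes.items()},
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_keypoints_json(path: str | Path) -> tuple[KeypointSet, dict]:
    data = json.loads(Path(path).read_text())
    kp = data["keypoints"]
    keypoints = KeypointSet(
        nose_tip=tuple(kp["nose"]), eyebrow_mid=tuple(kp["eyebrow"]),
        upper_lip=tuple(kp["upper_lip"]), lower_lip=tuple(kp["lower_lip"]))
    return keypoints, data


def trajectories_to_frame(trajectories: TrajectorySet, token_id: int = 0) -> pd.DataFrame:
    rows = []
    for name in KEYPOINT_NAMES:
        pos = trajectories.positions[name]
        lost = trajectories.lost[name]
        for frame in range(len(pos)):
            rows.append({
                "token_id": token_id, "frame": frame, "keypoint": name,
                "x": pos[frame, 0], "y": pos[frame, 1],
                "compensated": trajectories.compensated,
                "lost": bool(lost[frame]),
            })
    return pd.DataFrame(rows, columns=["token_id", "frame", "keypoint",
                                       "x", "y", "compensated", "lost"])


def write_trajectories_csv(trajectories: TrajectorySet, path: str | Path,
                           token_id: int = 0) -> None:
    trajectories_to_frame(trajectories, token_id).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path, fps: float = 29.97,
                          ) -> dict[int, TrajectorySet]:
    """Load a trajectories CSV back into per-token TrajectorySets."""
    frame = pd.read_csv(path)
    out = {}
    for token_id, group in frame.groupby("token_id"):
        positions = {}
        lost = {}
        compensated = bool(group["compensated"].iloc[0])
        for name, sub in group.groupby("keypoint"):
            sub = sub.sort_values("frame")
            positions[name] = sub[["x", "y"]].to_numpy(float)
            lost[name] = sub["lost"].to_numpy(bool)
        out[int(token_id)] = TrajectorySet(positions=positions, fps=fps,
                                           compensated=compensated, lost=lost)
    return out
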