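"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

import facekin as fk


@pytest.fixture(scope="session")
def scripted_video():
    """A 40-frame 270x480 talking face with head, brow and lip motion."""
    spec = fk.FaceSceneSpec.scripted(height=270, width=480, n_frames=40, seed=0)
    return fk.render_face_video(spec)


@pytest.fixture(scope="session")
def scripted_detection(scripted_video):
    return fk.detect_keypoints(scripted_video[0])


@pytest.fixture(scope="session")
def scripted_trajectories(scripted_video, scripted_detection):
    return fk.track_keypoints(scripted_video, scripted_detection.keypoints,
                              fps=scripted_video.fps)


@pytest.fixture(scope="session")
def static_video():
    """A 6-frame resting face (all waveforms zero)."""
    spec = fk.FaceSceneSpec(height=270, width=480, n_frames=6)
    return fk.render_face_video(spec)


@pytest.fixture(scope="session")
def translating_video():
    """A face translating 1 px/frame downward, no articulation."""
    T = 20
    spec = fk.FaceSceneSpec(height=270, width=480, n_frames=T,
                            head_y=np.arange(T, dtype=float))
    return fk.render_face_video(spec)
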