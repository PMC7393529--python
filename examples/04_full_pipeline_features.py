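"""Run the whole pipeline and read off the 33 articulatory features.

Segments a two-token synthetic recording by its audio, detects and
tracks the keypoints per token, removes head motion, and extracts the
head-size-normalized feature vector for every token.
"""

import numpy as np

import facekin as fk

audio, _ = fk.synth_token_audio(n_tokens=2, token_length_s=0.8, gap_s=1.0,
                                rate=16000, peak=1.0, noise_floor=0.01,
                                seed=3)
n_frames = int(np.ceil(audio.duration * 29.97))
# 540x960 keeps the mouth large enough for the 31-px tracking window
video = fk.render_face_video(fk.FaceSceneSpec.scripted(
    height=540, width=960, n_frames=n_frames))

result = fk.run_token_pipeline(video, audio)

print(f"processed {len(result.features)} tokens; "
      f"feature table shape: {result.features.shape}")
cols = ["token_id", "f05_eyebrow_max_raise", "f09_lips_max_raise",
        "f21_lips_t_max_raise", "f31_lips_max_vel_raise", "normalizer_px"]
print("\nselected columns:")
print(result.features[cols].round(4).to_string(index=False))
print("\nDistances are in head-size units (divide-by-normalizer), times"
      " are relative (0 = token start, 1 = token end), velocities are"
      " head-size units per second.")
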