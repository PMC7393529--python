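"""Segment word tokens out of a continuous recording using its audio.

Builds a synthetic 16 kHz recording with three noise-burst "utterances"
over a quiet noise floor, then thresholds the median-filtered
short-time energy at 20% of its maximum to cut the video into buffered
per-token frame intervals.
"""

import facekin as fk

audio, truth = fk.synth_token_audio(n_tokens=3, token_length_s=0.7,
                                    gap_s=1.0, rate=16000, peak=0.9,
                                    noise_floor=0.02, seed=42)
segments = fk.segment_tokens(audio)

print(f"recording: {audio.duration:.2f} s at {audio.rate:.0f} Hz")
print(f"found {len(segments)} tokens (ground truth: {len(truth)} bursts)\n")
print("token  frames           audio samples      burst (truth)")
for i, (seg, (s0, s1)) in enumerate(zip(segments, truth)):
    print(f"{i:>5}  [{seg.start_frame:>4}, {seg.end_frame:>4})   "
          f"[{seg.start_sample:>6}, {seg.end_sample:>6})   [{s0}, {s1})")
print("\nEach frame interval covers its burst plus a 10-frame buffer on"
      " both sides; frames are 29.97 fps, so the buffer is ~0.33 s.")
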