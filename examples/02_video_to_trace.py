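"""Render a short trans-illumination video of a pulsating heart and pull the
contraction waveform back out with active/reference region differencing.

The dominant Fourier frequency of the extracted trace should sit at the
generating beat rate (80 beats/min = 1.333 Hz), demonstrating that the
active-minus-reference projection isolates the cardiac signal.
"""

import numpy as np

from spatbeat import (
    ROISpec,
    VideoScene,
    detect_beats,
    extract_trace,
    make_beat_train,
    make_video,
)

scene = VideoScene()  # 128x128 px, 60 fps, heart disc inside the shell
train = make_beat_train(80.0, duration_s=15.0, jitter_sd_ms=10.0, seed=3)
frames, truth = make_video(train, scene, duration_s=15.0, seed=4)

roi = ROISpec(
    active=(*scene.active_point, 4.0),
    reference=(*scene.reference_point, 4.0),
)
trace = extract_trace(frames, roi)
beats = detect_beats(trace)

spectrum = np.abs(np.fft.rfft(trace.values - trace.values.mean()))
freqs = np.fft.rfftfreq(trace.n_samples, d=1.0 / trace.sample_rate)
peak = freqs[np.argmax(spectrum)]

print(f"frames rendered        : {frames.n_frames} at {frames.frame_rate:.0f} fps")
print(f"ground-truth beats     : {truth.size}")
print(f"beats detected on trace: {len(beats)}")
print(f"dominant trace freq    : {peak:.3f} Hz (beat rate 1.333 Hz)")
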