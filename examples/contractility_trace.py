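"""Quantify beating in a synthetic cardiomyocyte monolayer video.

Builds a 60 s, 25 fps phase-contrast-like video with one beating cluster
(20 doublets/min), runs the frame-difference motion analysis and prints the
event statistics a contractility assay would report.
"""
import numpy as np

from cardiomech.contractility import (
    baseline_correct,
    detect_motion_periods,
    frame_difference_trace,
    motion_map,
    summarize_contractility,
)
from cardiomech.synth import BeatSpec, ClusterSpec, generate_beating_video

spec = BeatSpec(
    duration=60.0,
    clusters=[ClusterSpec(center=(64, 64), radius=15, beat_period=3.0, doublet_gap=0.25)],
    seed=1,
)
video, truth = generate_beating_video(spec)

trace = baseline_correct(frame_difference_trace(video))
events = detect_motion_periods(trace, threshold=0.1)
summary = summarize_contractility(events, video.duration)
mmap = motion_map(video, window=60.0)

print(f"trace length: {len(trace)} samples ({video.n_frames} frames)")
print(f"detected motion events: {summary.n_events} (truth: {len(truth)} bursts)")
print(f"frequency: {summary.frequency:.1f} events/min")
print(f"mean contraction-cycle width: {summary.mean_width:.3f} s")
print(f"mean peak amplitude: {summary.mean_amplitude:.3f} intensity units")
active_px = np.count_nonzero(mmap.map > 1.5 * np.median(mmap.map))
print(f"motion map: {active_px} px well above the noise floor (cluster area ~709 px)")
# Each beat shows as a contraction/relaxation doublet, so events/min is
# twice the beat rate; the width is the supra-threshold duration of one
# burst, and the motion map localises the active cluster.
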