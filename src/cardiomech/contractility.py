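"""Frame-difference contractility analysis of beating monolayers.

For a video of n frames the per-pixel absolute intensity change between
consecutive frames, |I_k - I_{k-1}|, is averaged over the field of view to
give a length n-1 motion trace: a surrogate for the amount of motion
between two time points that is sensitive even to sub-resolution movement,
because it works on intensity fluctuations rather than edges. Periods of
contractile activity appear as peak-doublets (contraction burst, then
relaxation burst). The trace is baseline-adjusted to zero with a linear
fit, and maximal contiguous runs above a threshold (default 0.1) become
motion periods, from which peak amplitude, width (contraction cycle
duration) and frequency are summarised. Per-pixel integration of |dI| over
a time window maps where in the monolayer motion occurs, and per-ROI traces
cross-correlated against each other expose inter-cluster activation delays
of hundreds of milliseconds.
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np

from .datatypes import (
    ContractilitySummary,
    MotionEvent,
    MotionMap,
    MotionTrace,
    VideoStack,
    sem,
)

__all__ = [
    "frame_difference_trace",
    "motion_map",
    "baseline_correct",
    "detect_motion_periods",
    "summarize_contractility",
    "cluster_synchrony",
]


def frame_difference_trace(
    video: VideoStack, roi: Optional[np.ndarray] = None
) -> MotionTrace:
    """Mean |I_k - I_{k-1}| per frame pair, optionally restricted to a ROI."""
    frames = video.frames
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != frames.shape[1:]:
            raise ValueError("ROI shape must match the frame shape")
        if not roi.any():
            raise ValueError("ROI is empty")
        frames = frames[:, roi]
    diff = np.abs(np.diff(frames, axis=0))
    values = diff.reshape(diff.shape[0], -1).mean(axis=1)
    return MotionTrace(values=values, frame_rate=video.frame_rate)


def motion_map(video: VideoStack, window: float) -> MotionMap:
    """Per-pixel sum of |dI| over all frame pairs inside ``window`` seconds."""
    if window <= 0:
        raise ValueError("window must be positive")
    if window > video.duration + 1e-9:
        raise ValueError(
            f"window {window} s exceeds the video duration {video.duration} s"
        )
    n_pairs = min(int(math.floor(window * video.frame_rate)), video.n_frames - 1)
    diff = np.abs(np.diff(video.frames[: n_pairs + 1], axis=0))
    return MotionMap(map=diff.sum(axis=0), window=window)


def baseline_correct(trace: MotionTrace) -> MotionTrace:
    """Zero the trace baseline with a linear fit to its quiescent samples.

    Peaks would bias a fit through the whole trace, so the line is fitted by
    ordinary least squares to the samples at or below the trace median, then
    re-fitted once on the residual's own below-median samples (two passes).
    """
    v = trace.values.astype(float).copy()
    if v.size < 2:
        raise ValueError("need at least two samples to fit a baseline")
    t = np.arange(v.size, dtype=float)
    for _ in range(2):
        quiescent = v <= np.median(v)
        if quiescent.sum() < 2:  # constant trace
            v = v - v.mean()
            break
        coeffs = np.polyfit(t[quiescent], v[quiescent], 1)
        v = v - np.polyval(coeffs, t)
    return MotionTrace(values=v, frame_rate=trace.frame_rate, baseline_removed=True)


def detect_motion_periods(
    trace: MotionTrace, threshold: float = 0.1, merge_gap: float = 0.0
) -> List[MotionEvent]:
    """Segment the corrected trace into maximal supra-threshold runs.

    Each maximal contiguous run of samples strictly above ``threshold`` is
    one motion period; a contraction/relaxation doublet that dips below
    threshold in between therefore counts as two events, unless
    ``merge_gap`` (seconds) is raised to fuse runs separated by at most that
    much sub-threshold time.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not trace.baseline_removed:
        raise ValueError("detect_motion_periods expects a baseline-corrected trace")
    above = trace.values > threshold
    runs = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # optional fusing of runs separated by short sub-threshold gaps
    gap_samples = int(round(merge_gap * trace.frame_rate))
    if gap_samples > 0 and runs:
        merged = [runs[0]]
        for start, end in runs[1:]:
            if start - merged[-1][1] <= gap_samples:
                merged[-1] = (merged[-1][0], end)
            else:
                merged.append((start, end))
        runs = merged
    events = []
    for start, end in runs:
        events.append(
            MotionEvent(
                start_frame=start,
                end_frame=end,
                peak_amplitude=float(trace.values[start:end].max()),
                width=(end - start) / trace.frame_rate,
            )
        )
    return events


def summarize_contractility(
    events: Sequence[MotionEvent], trace_duration: float, events_per_beat: int = 1
) -> ContractilitySummary:
    """Average event amplitude, width and rate over the whole trace.

    ``frequency`` is events per minute; set ``events_per_beat=2`` to report
    doublets (contraction + relaxation pairs) per minute instead of
    threshold runs per minute.
    """
    if trace_duration <= 0:
        raise ValueError("trace_duration must be positive")
    if events_per_beat < 1:
        raise ValueError("events_per_beat must be at least 1")
    n = len(events)
    if n == 0:
        nan = float("nan")
        return ContractilitySummary(
            mean_amplitude=nan,
            sem_amplitude=nan,
            mean_width=nan,
            sem_width=nan,
            frequency=0.0,
            n_events=0,
            trace_duration=trace_duration,
        )
    amplitudes = np.array([e.peak_amplitude for e in events])
    widths = np.array([e.width for e in events])
    return ContractilitySummary(
        mean_amplitude=float(amplitudes.mean()),
        sem_amplitude=sem(amplitudes),
        mean_width=float(widths.mean()),
        sem_width=sem(widths),
        frequency=(n / events_per_beat) / (trace_duration / 60.0),
        n_events=n,
        trace_duration=trace_duration,
    )


def cluster_synchrony(
    video: VideoStack, rois: Sequence[np.ndarray], max_lag: float = 0.5
) -> np.ndarray:
    """Pairwise activation lags (s) between regions of interest.

    Each ROI gets its own baseline-corrected frame-difference trace; the lag
    of ROI j relative to ROI i is the argmax of their normalised
    cross-correlation over lags up to ``max_lag`` seconds, at frame
    resolution (positive when j starts later than i). The matrix is
    antisymmetric by construction. Beat trains are periodic, so ``max_lag``
    must stay below half the beat period for the maximum to be unambiguous.
    """
    if len(rois) < 2:
        raise ValueError("need at least two ROIs")
    masks = [np.asarray(r, dtype=bool) for r in rois]
    for a in range(len(masks)):
        if not masks[a].any():
            raise ValueError(f"ROI {a} is empty")
        for b in range(a + 1, len(masks)):
            if np.any(masks[a] & masks[b]):
                raise ValueError(f"ROIs {a} and {b} overlap")

    traces = [
        baseline_correct(frame_difference_trace(video, roi=m)).values for m in masks
    ]
    n = traces[0].size
    max_shift = int(round(max_lag * video.frame_rate))
    if max_shift < 1 or max_shift >= n:
        raise ValueError("max_lag out of range for this trace length")

    lags = np.zeros((len(masks), len(masks)))
    shifts = np.arange(-max_shift, max_shift + 1)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            a, b = traces[i], traces[j]
            best_corr, best_shift = -np.inf, 0
            for s in shifts:
                if s >= 0:
                    seg_a, seg_b = a[: n - s], b[s:]
                else:
                    seg_a, seg_b = a[-s:], b[: n + s]
                denom = np.linalg.norm(seg_a) * np.linalg.norm(seg_b)
                if denom == 0:
                    continue
                c = float(np.dot(seg_a, seg_b) / denom)
                if c > best_corr:
                    best_corr, best_shift = c, s
            lags[i, j] = best_shift / video.frame_rate
            lags[j, i] = -lags[i, j]
    return lags
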