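"""Core containers shared across the pipeline.

Intensities are kept as floating point on the acquisition scale
(``bit_scale`` records the nominal maximum); quantisation happens only on
export, never inside an analysis step.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class VideoStack:
    """A T x H x W grayscale image stack with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity frames, non-negative, time first.
    frame_rate : float
        Acquisition rate in frames per second.
    pixel_size : float, optional
        Lateral pixel size in micrometres per pixel.
    bit_scale : float
        Nominal maximum intensity of the acquisition (e.g. 2**14 - 1).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: Optional[float] = None
    bit_scale: float = float(2**14 - 1)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if self.frames.shape[0] < 2:
            raise ValueError("a video needs at least two frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n_frames / frame_rate)."""
        return self.frames.shape[0] / self.frame_rate


@dataclass
class MotionTrace:
    """Mean absolute frame-to-frame intensity change, one value per frame pair."""

    values: np.ndarray
    frame_rate: float
    baseline_removed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.baseline_removed and np.any(self.values < 0):
            raise ValueError("raw |dI| trace values cannot be negative")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.frame_rate


@dataclass
class MotionMap:
    """Per-pixel accumulated |dI| over a stated time window (seconds)."""

    map: np.ndarray
    window: float

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if self.map.ndim != 2:
            raise ValueError("motion map must be two-dimensional")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass
class MotionEvent:
    """One motion period: a maximal contiguous supra-threshold run.

    Frames are a half-open interval [start_frame, end_frame) over trace
    samples; ``width`` is its duration in seconds.
    """

    start_frame: int
    end_frame: int
    peak_amplitude: float
    width: float

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")


@dataclass
class ContractilitySummary:
    """Per-trace event statistics; SEM = sd/sqrt(n), NaN when undefined."""

    mean_amplitude: float
    sem_amplitude: float
    mean_width: float
    sem_width: float
    frequency: float  # events per minute
    n_events: int
    trace_duration: float  # seconds


@dataclass
class ProbeSpec:
    """Spherical AFM probe: radius in metres, Poisson ratio of the sample."""

    radius: float = 2.385e-6
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("probe radius must be positive")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")


@dataclass
class ForceCurve:
    """Approach force curve: position (m, monotone increasing toward the
    sample) against measured force (N), with sample metadata."""

    position: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.position.shape != self.force.shape or self.position.ndim != 1:
            raise ValueError("position and force must be 1-D arrays of equal length")
        if self.position.size < 20:
            raise ValueError("a force curve needs at least 20 samples")
        d = np.diff(self.position)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("position must be strictly monotone")
        if np.all(d < 0):  # normalise to increasing-toward-sample order
            self.position = self.position[::-1].copy()
            self.force = self.force[::-1].copy()


@dataclass
class HertzFit:
    """Result of fitting the spherical-indenter contact model to one curve."""

    E: float  # Pa
    contact_point: float  # m
    baseline_offset: float  # N
    rms_residual: float  # N
    contact_point_deviation: float  # m
    accepted: bool = False
    reject_reason: str = "none"  # one of {"rms", "contact_dev", "e_range", "none"}
    metadata: dict = field(default_factory=dict)


@dataclass
class GroupSummary:
    """Aggregated Young's modulus for one group (cell type x treatment x method)."""

    group: str
    mean_E: float
    sem_E: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n cannot be negative")


@dataclass
class Patch:
    """A segmented connected region with physical area and mean intensity."""

    id: int
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    area: float  # um^2
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area cannot be negative")


@dataclass
class RatioImage:
    """Pixelwise channel quotient, defined only where the denominator is
    above the validity floor."""

    ratio: np.ndarray
    valid_mask: np.ndarray
    mean_ratio: float

    def __post_init__(self) -> None:
        if self.ratio.shape != self.valid_mask.shape:
            raise ValueError("ratio map and mask shapes must agree")


@dataclass
class MitoNetworkRecord:
    """A mitochondrial network with its size class (boundary 100 um^2,
    'small' includes the boundary)."""

    area: float
    mean_intensity: float
    size_class: str  # "small" or "large"

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area cannot be negative")
        expected = "small" if self.area <= 100.0 else "large"
        if self.size_class != expected:
            raise ValueError(
                f"size_class {self.size_class!r} inconsistent with area {self.area}"
            )


@dataclass
class ComparisonResult:
    """Outcome of a group-comparison test with the caption star convention."""

    test: str
    groups: list
    statistic: float
    p_value: float
    pairwise: Optional["object"] = None  # DataFrame for >= 3 groups
    stars: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value must lie in [0, 1]")


def significance_stars(p: float) -> str:
    """Star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def sem(x: np.ndarray) -> float:
    """Standard error of the mean, sd/sqrt(n); NaN for n < 2."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))
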