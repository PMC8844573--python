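"""Synthetic input generators with recorded ground truth.

Every downstream stage of the pipeline (contractility, AFM elasticity,
image quantification) is exercised on data built here, so each generator
returns both the artefact and a truth record. All randomness flows from the
single ``seed`` carried by the spec; identical spec + seed gives
bit-identical output.

The beating-monolayer generator emulates 14-bit phase-contrast acquisition
of a cardiomyocyte monolayer at 25 fps: each active cell cluster emits one
contraction burst and one relaxation burst per beat (the peak-doublet
signature), with optional per-cluster phase delays of hundreds of
milliseconds and additive Gaussian pixel noise. Bursts are Gaussian-in-time
intensity perturbations; cluster pixels flip the sign of the perturbation
on alternate frames so that the mean |dI| trace traces out the burst
envelope deterministically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ForceCurve, ProbeSpec, VideoStack
from .afm import hertz_force

__all__ = [
    "ClusterSpec",
    "BeatSpec",
    "CurveSpec",
    "ObjectSpec",
    "ImageSpec",
    "RatioPair",
    "generate_beating_video",
    "generate_force_curve",
    "generate_labeled_image",
    "generate_ratio_pair",
    "generate_striation_image",
]


# ---------------------------------------------------------------------------
# beating monolayer video


@dataclass
class ClusterSpec:
    """One beating cell cluster.

    center : (row, col) pixel position of the cluster centre
    radius : cluster radius in pixels (>= 1)
    beat_period : seconds between beats
    doublet_gap : seconds between the contraction and relaxation bursts
    phase_delay : seconds before the cluster's first beat
    motion_amplitude : peak intensity perturbation at the cluster pixels
    """

    center: Tuple[float, float]
    radius: float
    beat_period: float
    doublet_gap: float
    phase_delay: float = 0.0
    motion_amplitude: float = 6.0

    def __post_init__(self) -> None:
        if not self.beat_period > self.doublet_gap > 0:
            raise ValueError("need beat_period > doublet_gap > 0")
        if self.phase_delay < 0:
            raise ValueError("phase_delay must be non-negative")
        if self.radius < 1:
            raise ValueError("cluster radius must be at least 1 px")


@dataclass
class BeatSpec:
    """Acquisition and physiology parameters for a synthetic beating video."""

    frame_rate: float = 25.0
    duration: float = 120.0
    image_shape: Tuple[int, int] = (128, 128)
    clusters: List[ClusterSpec] = field(default_factory=list)
    noise_sd: float = 0.5
    bit_scale: float = float(2**14 - 1)
    background: float = 100.0
    burst_sd: float = 0.04  # seconds; temporal sd of one burst
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")
        if self.burst_sd <= 0:
            raise ValueError("burst_sd must be positive")


def _cluster_mask(shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _burst_envelope(t: np.ndarray, t_center: float, amplitude: float, sd: float) -> np.ndarray:
    """Truncated (+-3 sd) Gaussian-in-time burst envelope."""
    env = amplitude * np.exp(-0.5 * ((t - t_center) / sd) ** 2)
    env[np.abs(t - t_center) > 3.0 * sd] = 0.0
    return env


def generate_beating_video(spec: BeatSpec) -> Tuple[VideoStack, pd.DataFrame]:
    """Render a beating-monolayer video and its ground-truth burst table.

    Each cluster beats ``floor((duration - phase_delay)/beat_period)`` times;
    each beat contributes a contraction burst and, ``doublet_gap`` later, a
    relaxation burst. The truth table lists, per burst: cluster id, beat
    index, phase, centre time, and the half-open video-frame interval where
    the burst envelope is at or above half its peak (its FWHM span).
    """
    shape = tuple(spec.image_shape)
    for i, cl in enumerate(spec.clusters):
        r0, c0 = cl.center
        if (
            r0 - cl.radius < 0
            or c0 - cl.radius < 0
            or r0 + cl.radius > shape[0] - 1
            or c0 + cl.radius > shape[1] - 1
        ):
            raise ValueError(
                f"cluster {i} (center {cl.center}, radius {cl.radius}) "
                f"extends outside the {shape} image"
            )

    n_frames = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    rng = np.random.default_rng(spec.seed)

    frames = np.full((n_frames,) + shape, spec.background, dtype=float)
    signs = np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)
    half_width = spec.burst_sd * math.sqrt(2.0 * math.log(2.0))  # FWHM half-width

    records = []
    for ci, cl in enumerate(spec.clusters):
        mask = _cluster_mask(shape, cl.center, cl.radius)
        n_beats = int(math.floor((spec.duration - cl.phase_delay) / cl.beat_period))
        envelope = np.zeros(n_frames)
        for j in range(n_beats):
            t_beat = cl.phase_delay + j * cl.beat_period
            for phase, t_center in (
                ("contraction", t_beat),
                ("relaxation", t_beat + cl.doublet_gap),
            ):
                envelope += _burst_envelope(t, t_center, cl.motion_amplitude, spec.burst_sd)
                start = int(math.ceil((t_center - half_width) * spec.frame_rate))
                end = int(math.floor((t_center + half_width) * spec.frame_rate)) + 1
                records.append(
                    {
                        "cluster": ci,
                        "beat": j,
                        "phase": phase,
                        "t_center": t_center,
                        "start_frame": max(start, 0),
                        "end_frame": min(end, n_frames),
                    }
                )
        # alternate-sign modulation: |I_k - I_{k-1}| at cluster pixels
        # reproduces (env_k + env_{k-1})/2, i.e. the burst envelope.
        frames[:, mask] += (signs * envelope / 2.0)[:, None]

    if spec.noise_sd > 0:
        frames += rng.normal(0.0, spec.noise_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)

    truth = pd.DataFrame(
        records,
        columns=["cluster", "beat", "phase", "t_center", "start_frame", "end_frame"],
    )
    video = VideoStack(frames=frames, frame_rate=spec.frame_rate, bit_scale=spec.bit_scale)
    return video, truth


# ---------------------------------------------------------------------------
# AFM force curves


@dataclass
class CurveSpec:
    """Forward model of one approach force curve.

    Positions run from 0 toward the sample; beyond ``contact_point_true``
    the force follows the spherical-indenter contact law in the true
    parameters, before it only the (possibly tilted) baseline. Units: Pa,
    m, N.
    """

    E_true: float = 1000.0
    contact_point_true: float = 1.0e-6
    probe_radius: float = 2.385e-6
    poisson: float = 0.5
    max_indentation: float = 0.5e-6
    n_points: int = 500
    noise_sd: float = 5.0e-12
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E_true <= 0:
            raise ValueError("E_true must be positive")
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if not 0.0 <= self.poisson < 0.5 and self.poisson != 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")
        if self.max_indentation <= 0:
            raise ValueError("max_indentation must be positive")
        if self.n_points < 20:
            raise ValueError("need at least 20 samples")


def generate_force_curve(spec: CurveSpec, metadata: Optional[dict] = None) -> ForceCurve:
    """Simulate an approach curve; truth parameters ride in the metadata."""
    rng = np.random.default_rng(spec.seed)
    z = np.linspace(0.0, spec.contact_point_true + spec.max_indentation, spec.n_points)
    delta = np.clip(z - spec.contact_point_true, 0.0, None)
    probe = ProbeSpec(radius=spec.probe_radius, poisson=spec.poisson)
    force = spec.baseline_offset + spec.baseline_slope * z + hertz_force(
        spec.E_true, probe, delta
    )
    if spec.noise_sd > 0:
        force = force + rng.normal(0.0, spec.noise_sd, size=force.shape)
    md = dict(metadata or {})
    md.update(
        E_true=spec.E_true,
        contact_point_true=spec.contact_point_true,
        probe_radius=spec.probe_radius,
        poisson=spec.poisson,
        mode="indentation",
    )
    return ForceCurve(position=z, force=force, metadata=md)


# ---------------------------------------------------------------------------
# labelled fluorescence images


@dataclass
class ObjectSpec:
    """One image object: a filled disk or axis-aligned rectangle.

    geometry : ("disk", (row, col), radius_px) or
               ("rect", (row, col), (height_px, width_px)) with (row, col)
               the top-left corner for rectangles, the centre for disks
    mean_intensity : added intensity inside the object mask
    intensity_sd : per-pixel Gaussian spread of the object's own intensity
    """

    geometry: tuple
    mean_intensity: float
    intensity_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_intensity < 0 or self.intensity_sd < 0:
            raise ValueError("intensities must be non-negative")


@dataclass
class ImageSpec:
    """A synthetic single-channel fluorescence image."""

    shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 1.0  # um per px
    objects: List[ObjectSpec] = field(default_factory=list)
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.background < 0 or self.noise_sd < 0:
            raise ValueError("background and noise_sd must be non-negative")


def _object_mask(shape: Tuple[int, int], geometry: tuple) -> np.ndarray:
    kind = geometry[0]
    if kind == "disk":
        _, center, radius = geometry
        mask = _cluster_mask(shape, center, radius)
    elif kind == "rect":
        _, (r0, c0), (h, w) = geometry
        if r0 < 0 or c0 < 0 or r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValueError("rectangle extends outside the image")
        mask = np.zeros(shape, dtype=bool)
        mask[r0 : r0 + h, c0 : c0 + w] = True
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")
    if not mask.any():
        raise ValueError("object mask is empty")
    return mask


def generate_labeled_image(
    spec: ImageSpec,
) -> Tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build ``background + objects + noise`` with an exact truth record.

    Returns the image, an integer label mask (later objects overwrite
    earlier ones where they overlap; the union of all objects is
    ``mask > 0``), and a per-object table with the exact pixel count, area
    in um^2, and the mean drawn intensity over the object's own mask.
    """
    rng = np.random.default_rng(spec.seed)
    image = np.full(spec.shape, spec.background, dtype=float)
    labels = np.zeros(spec.shape, dtype=int)
    masks = []
    for i, obj in enumerate(spec.objects, start=1):
        mask = _object_mask(spec.shape, obj.geometry)
        values = np.full(int(mask.sum()), obj.mean_intensity)
        if obj.intensity_sd > 0:
            values = values + rng.normal(0.0, obj.intensity_sd, size=values.size)
        image[mask] += values
        labels[mask] = i
        masks.append(mask)
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    np.clip(image, 0.0, None, out=image)

    rows = []
    for i, mask in enumerate(masks, start=1):
        n_px = int(mask.sum())
        rows.append(
            {
                "object": i,
                "n_pixels": n_px,
                "area_um2": n_px * spec.pixel_size**2,
                "mean_intensity": float(image[mask].mean()),
            }
        )
    truth = pd.DataFrame(rows, columns=["object", "n_pixels", "area_um2", "mean_intensity"])
    return image, labels, truth


@dataclass
class RatioPair:
    """A two-channel pair whose in-mask pixel ratio is known by construction."""

    aggregate: np.ndarray
    monomer: np.ndarray
    mask: np.ndarray
    ratio: float


def generate_ratio_pair(spec: ImageSpec, ratio: float) -> RatioPair:
    """Two-channel pair for ratiometric membrane-potential imaging.

    Inside every object mask the noiseless aggregate channel equals
    ``ratio`` times the noiseless monomer channel, pixel for pixel; outside
    the masks both channels share the background. Channel noise draws come
    from independent substreams of the spec seed.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    noiseless_spec = ImageSpec(
        shape=spec.shape,
        pixel_size=spec.pixel_size,
        objects=[
            ObjectSpec(o.geometry, o.mean_intensity, 0.0) for o in spec.objects
        ],
        background=spec.background,
        noise_sd=0.0,
        seed=spec.seed,
    )
    monomer, labels, _ = generate_labeled_image(noiseless_spec)
    mask = labels > 0
    aggregate = monomer.copy()
    aggregate[mask] = ratio * monomer[mask]
    if spec.noise_sd > 0:
        rng_a = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
        rng_m = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
        aggregate = np.clip(
            aggregate + rng_a.normal(0.0, spec.noise_sd, aggregate.shape), 0.0, None
        )
        monomer = np.clip(
            monomer + rng_m.normal(0.0, spec.noise_sd, monomer.shape), 0.0, None
        )
    return RatioPair(aggregate=aggregate, monomer=monomer, mask=mask, ratio=ratio)


# ---------------------------------------------------------------------------
# sarcomere striations


def generate_striation_image(
    period: float,
    pixel_size: float,
    shape: Tuple[int, int] = (256, 256),
    orientation: float = 0.0,
    amplitude: float = 100.0,
    offset: float = 120.0,
) -> np.ndarray:
    """Sinusoidal band pattern with a known peak-to-peak spacing.

    ``period`` is the band spacing in micrometres; ``orientation`` the angle
    of the band stripes in degrees from the image x-axis (0 deg: horizontal
    stripes, intensity varying down the rows). Periods at or below twice the
    pixel size are rejected as unresolvable.
    """
    if not math.isfinite(period) or period <= 0:
        raise ValueError("period must be a positive finite length")
    if period <= 2.0 * pixel_size:
        raise ValueError(
            f"period {period} um is not resolvable at {pixel_size} um/px"
        )
    rows, cols = np.mgrid[: shape[0], : shape[1]].astype(float)
    theta = math.radians(orientation)
    # projection onto the band normal (perpendicular to the stripes)
    s = (rows * math.cos(theta) + cols * math.sin(theta)) * pixel_size
    return offset + amplitude * np.cos(2.0 * math.pi * s / period)
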