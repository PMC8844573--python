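"""Readers and writers for the pipeline's on-disk formats.

Videos and images travel as TIFF (via tifffile); force curves as
two-column TSV (position in m, force in N) with ``# key = value`` metadata
headers; tables as CSV. Intensities are stored as written — quantisation to
integer types happens only here, never in analysis code.
"""
from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ForceCurve, VideoStack

__all__ = [
    "write_video_tiff",
    "read_video_tiff",
    "write_image_tiff",
    "read_image_tiff",
    "write_force_curve",
    "read_force_curve",
]

PathLike = Union[str, Path]


def write_video_tiff(path: PathLike, video: VideoStack) -> None:
    """Store a video stack as a multi-page float32 TIFF with rate metadata."""
    tifffile.imwrite(
        str(path),
        video.frames.astype(np.float32),
        metadata={
            "frame_rate": video.frame_rate,
            "pixel_size": video.pixel_size,
            "bit_scale": video.bit_scale,
        },
    )


def read_video_tiff(path: PathLike, frame_rate: float = None) -> VideoStack:
    """Load a multi-page TIFF; frame rate comes from metadata unless given."""
    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frame_rate is None:
        frame_rate = meta.get("frame_rate")
        if frame_rate is None:
            raise ValueError("no frame_rate in TIFF metadata; pass it explicitly")
    kwargs = {}
    if meta.get("pixel_size") is not None:
        kwargs["pixel_size"] = float(meta["pixel_size"])
    if meta.get("bit_scale") is not None:
        kwargs["bit_scale"] = float(meta["bit_scale"])
    return VideoStack(frames=np.asarray(frames, dtype=float), frame_rate=float(frame_rate), **kwargs)


def write_image_tiff(path: PathLike, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image_tiff(path: PathLike) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def write_force_curve(path: PathLike, curve: ForceCurve) -> None:
    """Two-column TSV (position m, force N) with '#'-prefixed metadata."""
    lines = [f"# {key} = {value}" for key, value in sorted(curve.metadata.items())]
    lines.append("# position_m\tforce_N")
    for z, f in zip(curve.position, curve.force):
        lines.append(f"{z:.9e}\t{f:.9e}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_force_curve(path: PathLike) -> ForceCurve:
    metadata = {}
    position, force = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = _parse_value(value.strip())
            continue
        z, f = line.split("\t")
        position.append(float(z))
        force.append(float(f))
    return ForceCurve(
        position=np.asarray(position), force=np.asarray(force), metadata=metadata
    )
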