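"""Fluorescence and densitometry quantification.

Covers the imaging arm of the pipeline: automatic thresholding (Li's
minimum cross-entropy for mitochondrial stains, Huang's fuzzy method for
cytoskeletal masks), connected-component patch segmentation, the
area-weighted mean fluorescence F = sum(A_i * Fbar_i) / sum(A_i),
small/large mitochondrial-network classification at 100 um^2, pixelwise
aggregate/monomer ratio imaging for membrane-potential dyes, per-nucleus
signal averaging, sarcomeric band-spacing measurement, and total-protein
(Ponceau) normalised Western-blot densitometry.
"""
from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_li
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .datatypes import MitoNetworkRecord, Patch, RatioImage, sem

__all__ = [
    "li_threshold",
    "huang_threshold",
    "despeckle",
    "to_8bit",
    "segment_patches",
    "weighted_mean_intensity",
    "classify_mito_networks",
    "jc1_ratio",
    "nuclear_mean_intensity",
    "band_spacing",
    "densitometry_normalize",
    "MN_SIZE_BOUNDARY",
]

MN_SIZE_BOUNDARY = 100.0  # um^2; networks up to this size are "small"


def _check_nonconstant(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if np.unique(image).size < 2:
        raise ValueError("thresholding needs at least two distinct intensity values")
    return image


def li_threshold(image: np.ndarray) -> float:
    """Minimum cross-entropy threshold (Li & Lee iterative scheme)."""
    image = _check_nonconstant(image)
    return float(threshold_li(image))


def huang_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Huang's fuzzy threshold: minimise the fuzzy Shannon entropy.

    For each candidate threshold the image is viewed as a fuzzy set whose
    membership at gray level g is 1 / (1 + |g - mu| / C), with mu the mean
    of g's side of the threshold and C the gray-level range; the threshold
    returned minimises sum_g h(g) * S(u(g)) with S the Shannon entropy
    function. Histogram-based, deterministic.
    """
    image = _check_nonconstant(image)
    lo, hi = float(image.min()), float(image.max())
    hist, edges = np.histogram(image.ravel(), bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    c_range = hi - lo

    cum_w = np.cumsum(w)
    cum_wg = np.cumsum(w * centers)
    total_w, total_wg = cum_w[-1], cum_wg[-1]

    best_entropy, best_t = np.inf, centers[0]
    for t in range(n_bins - 1):
        w0, w1 = cum_w[t], total_w - cum_w[t]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = cum_wg[t] / w0
        mu1 = (total_wg - cum_wg[t]) / w1
        u = np.empty(n_bins)
        u[: t + 1] = 1.0 / (1.0 + np.abs(centers[: t + 1] - mu0) / c_range)
        u[t + 1 :] = 1.0 / (1.0 + np.abs(centers[t + 1 :] - mu1) / c_range)
        # Shannon entropy of the membership, weighted by the histogram
        with np.errstate(divide="ignore", invalid="ignore"):
            s = -u * np.log(u) - (1.0 - u) * np.log(1.0 - u)
        s[~np.isfinite(s)] = 0.0
        entropy = float(np.dot(w, s))
        if entropy < best_entropy:
            best_entropy = entropy
            best_t = 0.5 * (centers[t] + centers[t + 1])
    return float(best_t)


def despeckle(image: np.ndarray) -> np.ndarray:
    """3x3 median filter (the ImageJ 'despeckle' operation)."""
    return ndimage.median_filter(np.asarray(image, dtype=float), size=3)


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 255] with rounding, as an 8-bit conversion."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        raise ValueError("cannot 8-bit convert a constant image")
    return np.rint((image - lo) / (hi - lo) * 255.0).astype(np.uint8)


def segment_patches(
    image: np.ndarray, mask: np.ndarray, pixel_size: float = 1.0
) -> List[Patch]:
    """Connected components (8-connectivity) of ``mask`` as intensity patches."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes must agree")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    labels = sk_label(mask, connectivity=2)
    patches = []
    for prop in regionprops(labels, intensity_image=image):
        patches.append(
            Patch(
                id=int(prop.label),
                pixels=prop.coords,
                area=float(prop.area) * pixel_size**2,
                mean_intensity=float(prop.intensity_mean),
            )
        )
    return patches


def weighted_mean_intensity(patches: Sequence[Patch]) -> float:
    """Area-weighted mean fluorescence, F = sum(A_i * Fbar_i) / sum(A_i)."""
    if len(patches) == 0:
        raise ValueError("need at least one patch")
    areas = np.array([p.area for p in patches], dtype=float)
    means = np.array([p.mean_intensity for p in patches], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("total patch area must be positive")
    return float(np.dot(areas, means) / total)


def classify_mito_networks(
    patches: Sequence[Patch], boundary: float = MN_SIZE_BOUNDARY
) -> List[MitoNetworkRecord]:
    """Split mitochondrial networks into small (area <= boundary) and large."""
    records = []
    for p in patches:
        if p.area < 0:
            raise ValueError("patch area cannot be negative")
        records.append(
            MitoNetworkRecord(
                area=p.area,
                mean_intensity=p.mean_intensity,
                size_class="small" if p.area <= boundary else "large",
            )
        )
    return records


def jc1_ratio(
    aggregate_img: np.ndarray,
    monomer_img: np.ndarray,
    floor: Optional[float] = None,
) -> RatioImage:
    """Pixelwise aggregate/monomer ratio over the valid monomer mask.

    The ratio is defined only where the monomer signal exceeds ``floor``
    (default: the monomer image's Li threshold, which keeps near-zero
    denominators out); the summary is the mean ratio over that mask, NaN if
    the mask is empty.
    """
    aggregate_img = np.asarray(aggregate_img, dtype=float)
    monomer_img = np.asarray(monomer_img, dtype=float)
    if aggregate_img.shape != monomer_img.shape:
        raise ValueError("channel shapes must agree")
    if floor is None:
        floor = li_threshold(monomer_img)
    if floor < 0:
        raise ValueError("floor must be non-negative")
    valid = monomer_img > floor
    ratio = np.full(monomer_img.shape, np.nan)
    np.divide(aggregate_img, monomer_img, out=ratio, where=valid)
    mean_ratio = float(ratio[valid].mean()) if valid.any() else float("nan")
    return RatioImage(ratio=ratio, valid_mask=valid, mean_ratio=mean_ratio)


def nuclear_mean_intensity(
    nuclei_mask: np.ndarray, signal_img: np.ndarray
) -> Tuple[np.ndarray, float]:
    """Mean marker signal per nucleus, then averaged across nuclei.

    Nuclei are the 8-connected components of ``nuclei_mask``; the reported
    value is the mean of the per-nucleus means (instance averaging), not the
    pooled pixel mean.
    """
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    signal_img = np.asarray(signal_img, dtype=float)
    if nuclei_mask.shape != signal_img.shape:
        raise ValueError("mask and image shapes must agree")
    labels = sk_label(nuclei_mask, connectivity=2)
    n = labels.max()
    if n == 0:
        raise ValueError("no nuclei found in the mask")
    per_nucleus = ndimage.mean(signal_img, labels=labels, index=np.arange(1, n + 1))
    per_nucleus = np.asarray(per_nucleus, dtype=float)
    return per_nucleus, float(per_nucleus.mean())


def band_spacing(
    image: np.ndarray, pixel_size: float, min_prominence_frac: float = 0.1
) -> Tuple[float, float]:
    """Mean peak-to-peak band spacing (um) +- SEM of the spacings.

    The dominant band orientation is estimated from image-gradient
    statistics (the mean structure tensor); pixel intensities are projected
    onto the band normal and binned into a 1-px profile, whose peak-to-peak
    distances give the spacing. Requires at least three detectable bands.
    """
    image = np.asarray(image, dtype=float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    gy, gx = np.gradient(image)
    jxx, jyy, jxy = np.mean(gx * gx), np.mean(gy * gy), np.mean(gx * gy)
    # orientation of the dominant gradient direction = band normal
    theta = 0.5 * math.atan2(2.0 * jxy, jxx - jyy)
    ny, nx = math.sin(theta), math.cos(theta)
    # gradients point along the normal in (col, row) = (x, y) coordinates
    rows, cols = np.mgrid[: image.shape[0], : image.shape[1]].astype(float)
    proj = cols * nx + rows * ny
    proj -= proj.min()
    bins = np.rint(proj).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=image.ravel())
    profile = sums[counts > 0] / counts[counts > 0]
    prominence = min_prominence_frac * float(np.ptp(profile))
    peaks, _ = find_peaks(profile, prominence=prominence if prominence > 0 else None)
    if peaks.size < 3:
        raise ValueError("fewer than three bands detected")
    spacings = np.diff(peaks).astype(float) * pixel_size
    return float(spacings.mean()), sem(spacings)


def densitometry_normalize(
    table: pd.DataFrame,
    reference_group: str,
    fallback_group: Optional[str] = None,
) -> pd.DataFrame:
    """Total-protein-corrected blot intensities, normalised to a reference.

    Each band intensity is first divided by its lane's total protein
    (Ponceau stain), then, per protein, divided by the reference group's
    mean corrected value so the reference group averages exactly 1. If the
    reference group is absent or undetectable (non-positive mean) for a
    protein, ``fallback_group`` is used instead and recorded in the
    ``reference_used`` column.
    """
    required = {"sample", "protein", "band_intensity", "lane_total_protein"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"blot table is missing columns: {sorted(missing)}")
    if (table["lane_total_protein"] <= 0).any():
        raise ValueError("every lane must have a positive total-protein value")
    out = table.copy()
    out["corrected"] = out["band_intensity"] / out["lane_total_protein"]
    out["normalized"] = np.nan
    out["reference_used"] = ""
    for protein, sub in out.groupby("protein"):
        ref = reference_group
        ref_values = sub.loc[sub["sample"] == ref, "corrected"]
        if ref_values.empty or ref_values.mean() <= 0:
            if fallback_group is None:
                raise ValueError(
                    f"reference group {reference_group!r} undetectable for "
                    f"protein {protein!r} and no fallback given"
                )
            ref = fallback_group
            ref_values = sub.loc[sub["sample"] == ref, "corrected"]
            if ref_values.empty or ref_values.mean() <= 0:
                raise ValueError(
                    f"fallback group {fallback_group!r} also undetectable for "
                    f"protein {protein!r}"
                )
        out.loc[sub.index, "normalized"] = sub["corrected"] / ref_values.mean()
        out.loc[sub.index, "reference_used"] = ref
    return out
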