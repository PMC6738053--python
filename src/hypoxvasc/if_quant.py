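"""Hypoxia-marker (CAIX) quantification on tumour area.

The readout is fCAIX: the fraction of thresholded marker-positive pixels over
the analysable tumour area, after removing connected components of at most
``min_object_px`` pixels (non-specific speckle). A slide is called
CAIX-positive when fCAIX exceeds 1%.

Thresholds in the original workflow were set interactively above background
per sample; here three reproducible surrogates are offered: a
background-region statistic (mean + k*SD, default k=3), Otsu's bimodal split
over included pixels, or a fixed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from hypoxvasc.images import BinaryImage, ChannelImage, RegionMask

CAIX_MIN_OBJECT_PX = 5  # components of at most this many pixels are dropped
CAIX_POSITIVITY_CUTOFF = 0.01  # fCAIX strictly above this => CAIX-positive


@dataclass(frozen=True)
class CaixResult:
    """Per-slide CAIX quantification."""

    fcaix: float
    positive_pixels: int
    tumour_pixels: int
    threshold_used: float
    caix_positive: bool

    def __post_init__(self) -> None:
        if self.tumour_pixels <= 0:
            raise ValueError("tumour_pixels must be positive")
        if abs(self.fcaix - self.positive_pixels / self.tumour_pixels) > 1e-12:
            raise ValueError("fcaix must equal positive_pixels / tumour_pixels")

    def to_dict(self) -> dict:
        return {
            "fcaix": self.fcaix,
            "positive_pixels": self.positive_pixels,
            "tumour_pixels": self.tumour_pixels,
            "threshold_used": self.threshold_used,
            "caix_positive": self.caix_positive,
        }


def determine_threshold(
    image: ChannelImage,
    mask: RegionMask,
    method: str = "background",
    *,
    background_mask: RegionMask | None = None,
    k: float = 3.0,
    value: float | None = None,
) -> float:
    """Return one scalar segmentation threshold for a slide.

    method
        ``"background"`` — mean + ``k`` * SD over ``background_mask`` pixels
        (default k=3); ``"otsu"`` — automatic bimodal split over pixels
        included by ``mask``; ``"fixed"`` — return ``value`` unchanged.
    """
    mask.check_matches(image)
    if mask.n_included == 0:
        raise ValueError("mask includes no pixels")
    if method == "background":
        if background_mask is None:
            raise ValueError("background method requires a background_mask")
        background_mask.check_matches(image)
        bg = image.pixels[background_mask.include]
        if bg.size == 0:
            raise ValueError("background mask is empty")
        return float(bg.mean() + k * bg.std())
    if method == "otsu":
        vals = image.pixels[mask.include]
        return float(filters.threshold_otsu(vals))
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a value")
        return float(value)
    raise ValueError(f"unknown threshold method {method!r}")


def segment_above(image: ChannelImage, mask: RegionMask, threshold: float) -> BinaryImage:
    """Pixel positive iff included by the mask AND intensity strictly above threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    mask.check_matches(image)
    positive = mask.include & (image.pixels > threshold)
    return BinaryImage(positive, float(threshold), image.channel_label)


def filter_small_objects(
    binary: BinaryImage, min_pixels: int = CAIX_MIN_OBJECT_PX, connectivity: int = 2
) -> BinaryImage:
    """Remove connected components whose area does not exceed ``min_pixels``.

    "Exceeding" is read strictly: a component of exactly ``min_pixels`` pixels
    is removed, one of ``min_pixels + 1`` is kept. ``connectivity`` follows
    scikit-image (2 = 8-neighbour, the default; 1 = 4-neighbour).
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-nb) or 2 (8-nb)")
    if min_pixels == 0:
        return BinaryImage(binary.positive.copy(), binary.threshold, binary.channel_label, 0)
    labels = measure.label(binary.positive, connectivity=connectivity)
    if labels.max() == 0:
        kept = np.zeros_like(binary.positive)
    else:
        areas = np.bincount(labels.ravel())
        keep = areas > min_pixels
        keep[0] = False
        kept = keep[labels]
    return BinaryImage(kept, binary.threshold, binary.channel_label, min_pixels)


def compute_fcaix(
    binary: BinaryImage, mask: RegionMask, threshold_used: float | None = None
) -> CaixResult:
    """fCAIX = filtered positive pixels inside the mask / mask pixel count."""
    if binary.shape != mask.shape:
        raise ValueError("binary image and mask shapes differ")
    tumour_px = mask.n_included
    if tumour_px == 0:
        raise ValueError("empty tumour mask: fCAIX undefined")
    pos = int((binary.positive & mask.include).sum())
    fcaix = pos / tumour_px
    thr = binary.threshold if threshold_used is None else float(threshold_used)
    return CaixResult(fcaix, pos, tumour_px, thr, classify_caix(fcaix))


def classify_caix(fcaix: float, cutoff: float = CAIX_POSITIVITY_CUTOFF) -> bool:
    """CAIX-positive iff fCAIX strictly above the cutoff (default 1%)."""
    if not 0.0 <= fcaix <= 1.0:
        raise ValueError(f"fcaix must lie in [0, 1], got {fcaix}")
    return fcaix > cutoff


def quantify_caix(
    image: ChannelImage,
    mask: RegionMask,
    *,
    threshold_method: str = "otsu",
    min_object_px: int = CAIX_MIN_OBJECT_PX,
    connectivity: int = 2,
    background_mask: RegionMask | None = None,
    k: float = 3.0,
    fixed_value: float | None = None,
) -> CaixResult:
    """Full per-slide CAIX quantification: threshold, segment, filter, fCAIX."""
    thr = determine_threshold(
        image, mask, threshold_method, background_mask=background_mask, k=k, value=fixed_value
    )
    binary = segment_above(image, mask, thr)
    filtered = filter_small_objects(binary, min_object_px, connectivity)
    return compute_fcaix(filtered, mask, thr)
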