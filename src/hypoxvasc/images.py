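"""Raster containers for single-channel microscopy images.

Conventions used throughout the package: row-major grids, origin at the
top-left pixel, 0-based indices. A slide is represented by up to three
grey-scale channels (nuclei / vessel / hypoxia marker) plus a boolean
inclusion mask marking analysable tumour area (stroma, necrosis and large
vessels excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNEL_LABELS = ("nuclei", "vessel", "hypoxia")


@dataclass(frozen=True)
class ChannelImage:
    """One grey-scale channel of a scanned slide.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities.
    pixel_size
        Physical pixel edge length in micrometres.
    channel_label
        One of ``"nuclei"``, ``"vessel"``, ``"hypoxia"``.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_label: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        if self.channel_label not in CHANNEL_LABELS:
            raise ValueError(
                f"channel_label must be one of {CHANNEL_LABELS}, got {self.channel_label!r}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionMask:
    """Boolean inclusion mask; ``True`` marks analysable tumour area."""

    include: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        if inc.ndim != 2 or inc.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        object.__setattr__(self, "include", inc)

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape

    @property
    def n_included(self) -> int:
        return int(self.include.sum())

    def check_matches(self, image: ChannelImage) -> None:
        if self.shape != image.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match image shape {image.shape}"
            )


@dataclass(frozen=True)
class BinaryImage:
    """Segmentation result: boolean positivity grid with its provenance."""

    positive: np.ndarray
    threshold: float
    channel_label: str
    min_object_px: int = 0  # 0 means no size filter applied yet

    def __post_init__(self) -> None:
        pos = np.asarray(self.positive, dtype=bool)
        if pos.ndim != 2 or pos.size == 0:
            raise ValueError("positive must be a non-empty 2-D grid")
        object.__setattr__(self, "positive", pos)

    @property
    def shape(self) -> tuple[int, int]:
        return self.positive.shape

    @property
    def n_positive(self) -> int:
        return int(self.positive.sum())


def read_channel(path: str | Path, channel_label: str, pixel_size: float) -> ChannelImage:
    """Read a single-channel raster (TIFF/PNG) into a :class:`ChannelImage`.

    Raises
    ------
    ValueError
        If the file holds more than one channel, or cannot be decoded
        (a truncated file raises rather than returning silent zeros).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path) if path.suffix.lower() in {".tif", ".tiff"} else _read_other(path)
    except Exception as exc:  # decoding failure = format error, never silent zeros
        raise ValueError(f"cannot decode raster file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"{path} holds a {arr.ndim}-D array; expected a single-channel 2-D raster"
        )
    return ChannelImage(arr.astype(np.float64), pixel_size, channel_label)


def _read_other(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return iio.imread(path)


def write_channel(image: ChannelImage, path: str | Path) -> None:
    """Write a channel as a single-channel 16-bit TIFF."""
    arr = np.clip(np.rint(image.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), arr)


def read_mask(path: str | Path) -> RegionMask:
    """Read an inclusion mask (0 = excluded, anything else = included)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = _read_other(path)
    except Exception as exc:
        raise ValueError(f"cannot decode mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel 2-D")
    return RegionMask(arr > 0)


def write_mask(mask: RegionMask, path: str | Path) -> None:
    """Write a mask as 8-bit raster (0 = excluded, 255 = included)."""
    arr = np.where(mask.include, 255, 0).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
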