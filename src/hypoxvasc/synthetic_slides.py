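"""Synthetic dual-marker slides with exact pixel-level ground truth.

The generator emulates the structure the quantification pipeline relies on —
an analysable tumour region, a hypoxia-marker channel with a known positive
fraction, a vessel channel with discrete disjoint vessel objects (optionally
clustered into planted hotspots), and sub-threshold noise speckles at sizes
at or below the pipeline's exclusion cutoffs — without attempting
photorealism. Intensities follow a two-level model (constant background and
foreground plus Gaussian noise), the simplest model that exercises threshold
segmentation.

Ground truth is exact by construction: the recorded positive fraction is the
painted pixel count divided by the mask pixel count, and vessel objects are
pairwise disjoint, non-adjacent pixel sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from hypoxvasc.images import ChannelImage, RegionMask
from hypoxvasc.if_quant import CAIX_MIN_OBJECT_PX
from hypoxvasc.mvd import VESSEL_MIN_OBJECT_PX, VesselObject


@dataclass(frozen=True)
class HotspotSpec:
    """A planted dense vessel cluster: centre (row, col), radius, count."""

    centre: tuple[int, int]
    radius: float
    n_vessels: int


@dataclass
class SlideSimParams:
    """Parameters of one synthetic slide.

    Defaults describe a 768x768 frame at 4 µm/pixel (~3x3 mm of tissue, so
    three conventional 0.74 mm^2 counting fields fit without overlap) with a
    moderately hypoxic tumour occupying ~60% of the frame; intensity scales
    are free parameters of the generator (16-bit range), not calibrated to
    any scanner.
    """

    image_shape: tuple[int, int] = (768, 768)
    pixel_size: float = 4.0  # µm per pixel
    tumour_mask_fraction: float = 0.6
    true_caix_fraction: float = 0.1
    n_vessels: int = 40
    hotspot_spec: list[HotspotSpec] = field(default_factory=list)
    vessel_size_range: tuple[int, int] = (6, 40)  # pixels per vessel object
    noise_speckle_rate: float = 0.05  # speckles per 1000 pixels, per channel
    background_level: float = 100.0
    foreground_level: float = 1000.0
    noise_sigma: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.true_caix_fraction <= 1.0:
            raise ValueError("true_caix_fraction must lie in [0, 1]")
        if not 0.0 < self.tumour_mask_fraction <= 1.0:
            raise ValueError("tumour_mask_fraction must lie in (0, 1]")
        if self.foreground_level <= self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        if self.vessel_size_range[0] < 1 or self.vessel_size_range[1] < self.vessel_size_range[0]:
            raise ValueError("invalid vessel_size_range")
        if self.n_vessels < 0 or self.noise_speckle_rate < 0:
            raise ValueError("counts and rates must be non-negative")


@dataclass(frozen=True)
class SlideGroundTruth:
    """Exact painted-pixel bookkeeping for one synthetic slide."""

    tumour_mask: RegionMask
    caix_mask: np.ndarray  # painted marker-positive pixels (speckles excluded)
    true_positive_pixels: int
    true_caix_fraction: float
    vessel_objects: tuple[VesselObject, ...]
    per_region_vessel_counts: dict[int, int]  # hotspot index -> planted count

    def to_dict(self) -> dict:
        return {
            "true_positive_pixels": self.true_positive_pixels,
            "tumour_pixels": self.tumour_mask.n_included,
            "true_caix_fraction": self.true_caix_fraction,
            "n_vessels": len(self.vessel_objects),
            "per_region_vessel_counts": {
                str(k): v for k, v in self.per_region_vessel_counts.items()
            },
        }


# compact 8-connected growth order used for speckles and blob trimming
_SPIRAL = [(0, 0), (0, 1), (1, 0), (1, 1), (0, -1), (-1, 0), (1, -1), (-1, 1), (-1, -1)]


def _elliptical_mask(shape: tuple[int, int], target_fraction: float) -> np.ndarray:
    """Centred ellipse covering roughly ``target_fraction`` of the frame."""
    if target_fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    rows, cols = shape
    alpha = np.sqrt(4.0 * target_fraction / np.pi)
    a, b = alpha * rows / 2.0, alpha * cols / 2.0
    rr, cc = np.mgrid[0:rows, 0:cols]
    return ((rr - (rows - 1) / 2.0) / a) ** 2 + ((cc - (cols - 1) / 2.0) / b) ** 2 <= 1.0


def _ellipse_offsets(rng: np.random.Generator, area_px: int) -> np.ndarray:
    """Pixel offsets of a filled ellipse (aspect <= 2, random orientation)."""
    aspect = rng.uniform(1.0, 2.0)
    # solve pi*a*b = area with b = a/aspect
    a = np.sqrt(area_px * aspect / np.pi)
    b = a / aspect
    theta = rng.uniform(0, np.pi)
    extent = int(np.ceil(a)) + 1
    dr, dc = np.mgrid[-extent : extent + 1, -extent : extent + 1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.stack([dr[inside], dc[inside]], axis=1)


def _paint_caix(
    rng: np.random.Generator, mask: np.ndarray, target_px: int
) -> np.ndarray:
    """Paint compact blobs inside the mask totalling exactly ``target_px``."""
    painted = np.zeros_like(mask)
    if target_px == 0:
        return painted
    remaining = target_px
    unpainted_rows, unpainted_cols = np.nonzero(mask)
    while remaining > 0:
        avail = np.nonzero(mask & ~painted)
        if avail[0].size == 0:  # cannot happen while remaining <= mask sum
            raise RuntimeError("ran out of unpainted tumour pixels")
        i = rng.integers(avail[0].size)
        cr, cc = int(avail[0][i]), int(avail[1][i])
        area = int(rng.integers(CAIX_MIN_OBJECT_PX + 4, 80))
        offs = _ellipse_offsets(rng, area)
        rr = cr + offs[:, 0]
        cols = cc + offs[:, 1]
        ok = (
            (rr >= 0)
            & (rr < mask.shape[0])
            & (cols >= 0)
            & (cols < mask.shape[1])
        )
        rr, cols = rr[ok], cols[ok]
        new = mask[rr, cols] & ~painted[rr, cols]
        rr, cols = rr[new], cols[new]
        if rr.size == 0:
            continue
        if rr.size > remaining:
            # keep the pixels closest to the blob centre so the blob stays compact
            d2 = (rr - cr) ** 2 + (cols - cc) ** 2
            keep = np.argsort(d2, kind="stable")[:remaining]
            rr, cols = rr[keep], cols[keep]
        painted[rr, cols] = True
        remaining -= rr.size
    return painted


def _place_speckles(
    rng: np.random.Generator,
    shape: tuple[int, int],
    forbidden: np.ndarray,
    n_speckles: int,
    max_size: int,
) -> np.ndarray:
    """Place speckles of size <= max_size, never touching forbidden pixels."""
    speckles = np.zeros(shape, dtype=bool)
    blocked = ndimage.binary_dilation(forbidden, iterations=2)
    for _ in range(n_speckles):
        size = int(rng.integers(1, max_size + 1))
        for _attempt in range(50):
            r = int(rng.integers(shape[0]))
            c = int(rng.integers(shape[1]))
            px = [(r + dr, c + dc) for dr, dc in _SPIRAL[:size]]
            if all(
                0 <= pr < shape[0] and 0 <= pc < shape[1] and not blocked[pr, pc]
                for pr, pc in px
            ):
                for pr, pc in px:
                    speckles[pr, pc] = True
                    blocked[
                        max(0, pr - 2) : pr + 3, max(0, pc - 2) : pc + 3
                    ] = True
                break
    return speckles


def _paint_vessels(
    rng: np.random.Generator, params: SlideSimParams, mask: np.ndarray
) -> tuple[np.ndarray, list[VesselObject], dict[int, int]]:
    """Disjoint, non-adjacent vessel blobs; hotspot clusters first."""
    shape = params.image_shape
    vessel_mask = np.zeros(shape, dtype=bool)
    blocked = np.zeros(shape, dtype=bool)
    objects: list[VesselObject] = []
    per_region: dict[int, int] = {}
    lo, hi = params.vessel_size_range

    def place_one(centre_sampler) -> bool:
        for _attempt in range(200):
            cr, cc = centre_sampler()
            area = int(rng.integers(lo, hi + 1))
            offs = _ellipse_offsets(rng, area)
            rr = cr + offs[:, 0]
            cols = cc + offs[:, 1]
            if (
                rr.min() < 0
                or rr.max() >= shape[0]
                or cols.min() < 0
                or cols.max() >= shape[1]
            ):
                continue
            if blocked[rr, cols].any():
                continue
            vessel_mask[rr, cols] = True
            objects.append(VesselObject(len(objects), rr, cols))
            dil = np.zeros(shape, dtype=bool)
            dil[rr, cols] = True
            blocked[:] |= ndimage.binary_dilation(dil, iterations=2)
            return True
        return False

    hotspot_zones = np.zeros(shape, dtype=bool)
    for region_id, spec in enumerate(params.hotspot_spec):
        hr, hc = spec.centre
        if not mask[hr, hc]:
            raise ValueError(f"hotspot centre {spec.centre} lies outside the tumour mask")
        placed = 0
        for _ in range(spec.n_vessels):
            def in_disc():
                ang = rng.uniform(0, 2 * np.pi)
                rad = spec.radius * np.sqrt(rng.uniform())
                return int(round(hr + rad * np.sin(ang))), int(round(hc + rad * np.cos(ang)))

            if place_one(in_disc):
                placed += 1
        per_region[region_id] = placed
        rr, cc2 = np.mgrid[0 : shape[0], 0 : shape[1]]
        hotspot_zones |= (rr - hr) ** 2 + (cc2 - hc) ** 2 <= (spec.radius + hi) ** 2

    def anywhere():
        # keep background vessels out of planted hotspot zones so the
        # recorded per-region counts stay exact; give up after many tries
        for _ in range(1000):
            r = int(rng.integers(shape[0]))
            c = int(rng.integers(shape[1]))
            if not hotspot_zones[r, c]:
                return r, c
        return int(rng.integers(shape[0])), int(rng.integers(shape[1]))

    for _ in range(params.n_vessels):
        place_one(anywhere)
    return vessel_mask, objects, per_region


def _render(
    rng: np.random.Generator,
    painted: np.ndarray,
    params: SlideSimParams,
    label: str,
) -> ChannelImage:
    img = np.full(params.image_shape, params.background_level, dtype=np.float64)
    img[painted] = params.foreground_level
    if params.noise_sigma > 0:
        img += rng.normal(0.0, params.noise_sigma, size=params.image_shape)
    np.clip(img, 0.0, 65535.0, out=img)
    return ChannelImage(img, params.pixel_size, label)


def generate_slide(
    params: SlideSimParams,
) -> tuple[ChannelImage, ChannelImage, ChannelImage, SlideGroundTruth]:
    """Generate (nuclei, caix, vessel) channels plus exact ground truth.

    Reproducible: the seed fans out to independent substreams for the marker
    channel, the vessel channel, nuclei and the intensity noise, so the same
    seed yields byte-identical images.
    """
    params.validate()
    streams = np.random.SeedSequence(params.seed).spawn(4)
    rng_caix = np.random.default_rng(streams[0])
    rng_vessel = np.random.default_rng(streams[1])
    rng_nuclei = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])

    mask = _elliptical_mask(params.image_shape, params.tumour_mask_fraction)
    mask_px = int(mask.sum())
    target_px = int(round(params.true_caix_fraction * mask_px))
    if target_px > mask_px or (mask_px == 0 and params.true_caix_fraction > 0):
        max_reachable = 1.0 if mask_px else 0.0
        raise ValueError(
            "requested true_caix_fraction unreachable given the mask size: "
            f"maximum reachable fraction is {max_reachable:.3f}"
        )

    caix_painted = _paint_caix(rng_caix, mask, target_px)
    vessel_painted, vessel_objects, per_region = _paint_vessels(
        rng_vessel, params, mask
    )

    n_px = params.image_shape[0] * params.image_shape[1]
    n_speck = rng_noise.poisson(params.noise_speckle_rate * n_px / 1000.0)
    caix_speck = _place_speckles(
        rng_caix, params.image_shape, caix_painted, int(n_speck), CAIX_MIN_OBJECT_PX
    )
    vessel_speck = _place_speckles(
        rng_vessel, params.image_shape, vessel_painted, int(n_speck), VESSEL_MIN_OBJECT_PX
    )

    # nuclei: cosmetic scatter of small discs across the frame
    nuclei_painted = np.zeros(params.image_shape, dtype=bool)
    n_nuclei = max(1, n_px // 4000)
    for _ in range(n_nuclei):
        r = int(rng_nuclei.integers(params.image_shape[0]))
        c = int(rng_nuclei.integers(params.image_shape[1]))
        rr, cc = np.mgrid[
            max(0, r - 2) : min(params.image_shape[0], r + 3),
            max(0, c - 2) : min(params.image_shape[1], c + 3),
        ]
        nuclei_painted[rr, cc] |= (rr - r) ** 2 + (cc - c) ** 2 <= 4

    nuclei = _render(rng_noise, nuclei_painted, params, "nuclei")
    caix = _render(rng_noise, caix_painted | caix_speck, params, "hypoxia")
    vessel = _render(rng_noise, vessel_painted | vessel_speck, params, "vessel")

    truth = SlideGroundTruth(
        tumour_mask=RegionMask(mask),
        caix_mask=caix_painted,
        true_positive_pixels=target_px,
        true_caix_fraction=(target_px / mask_px) if mask_px else 0.0,
        vessel_objects=tuple(vessel_objects),
        per_region_vessel_counts=per_region,
    )
    return nuclei, caix, vessel, truth
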