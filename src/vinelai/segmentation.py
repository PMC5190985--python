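"""Sky/vegetation segmentation of below-canopy images.

Shots taken from below a vertically trained row canopy at a 57.5° zenith
view angle show the leaf wall against open sky.  Sky pixels are bright and
weakly saturated; foliage is darker except for sunlit leaves, which are
bright but strongly green.  Segmentation therefore works in
hue-saturation-brightness (HSB, i.e. HSV) space:

1. an Otsu threshold on the brightness channel selects sky candidates
   (clipped into a plausible sky-brightness band so that unimodal frames —
   pure sky or pure canopy — are not split in half by the threshold);
2. a chromatic guard reassigns bright but saturated green candidates back
   to vegetation.

The gap fraction P0 is the fraction of pixels labelled sky.  The whole
chain is deterministic and needs no per-image user input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import median_filter
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

__all__ = [
    "CanopyImage",
    "HSBImage",
    "SegmentationMask",
    "GapFractionResult",
    "SegmentationParams",
    "DEFAULT_SEGMENTATION",
    "load_image",
    "rgb_to_hsb",
    "segment_sky",
    "gap_fraction",
    "gap_fraction_of_image",
    "write_mask_png",
    "write_results_csv",
]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class CanopyImage:
    """A below-canopy RGB frame plus its acquisition metadata.

    ``pixels`` is an H×W×3 uint8 array.  ``side`` and ``offset_cm`` locate
    the replicate within the four-shot protocol (two row sides × offsets of
    20 and 40 cm from the pole).
    """

    pixels: np.ndarray
    view_angle_deg: float = 57.5
    side: str | None = None          # "left" | "right"
    offset_cm: float | None = None   # 20 or 40 by protocol
    vine_id: str | None = None
    area_id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class HSBImage:
    """Per-pixel hue (degrees in [0, 360)), saturation and brightness in [0, 1]."""

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.brightness.shape):
            raise ValueError("HSB channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


@dataclass
class SegmentationMask:
    """Boolean sky mask (True = sky) with its pixel counts."""

    mask: np.ndarray
    n_sky: int = field(init=False)
    n_total: int = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_sky = int(self.mask.sum())
        self.n_total = int(self.mask.size)


@dataclass
class GapFractionResult:
    """Gap fraction P0 = n_sky / n_total and a saturation flag (no sky seen)."""

    p0: float
    saturated: bool
    mask: SegmentationMask


# ---------------------------------------------------------------------------
# Parameters

SKY_REFERENCE_HSB = (210.0, 0.15, 0.95)   # clear-sky blue
LEAF_REFERENCE_HSB = (120.0, 0.80, 0.35)  # shaded green foliage


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds of the unsupervised sky rule.

    brightness_cut      fixed cut used when Otsu is undefined (constant
                        brightness channel)
    cut_band            the Otsu threshold is clipped into this interval;
                        brightness outside it is unambiguous sky/canopy
    green_hue_band      hue window (degrees) of the sunlit-leaf guard
    green_sat_min       minimum saturation for the guard to fire
    median_prefilter    optional 3×3 median filter against chroma artifacts
                        of lossy compression (off by default: keeps the
                        pipeline bit-reproducible on PNG input)
    """

    brightness_cut: float = 0.75
    cut_band: tuple[float, float] = (0.5, 0.85)
    green_hue_band: tuple[float, float] = (60.0, 180.0)
    green_sat_min: float = 0.5
    median_prefilter: bool = False


DEFAULT_SEGMENTATION = SegmentationParams()


# ---------------------------------------------------------------------------
# Operations


def load_image(path: str | Path, **meta) -> CanopyImage:
    """Read a PNG/JPEG file into a :class:`CanopyImage` (alpha dropped)."""
    with Image.open(path) as im:
        rgb = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return CanopyImage(pixels=rgb, **meta)


def rgb_to_hsb(image: CanopyImage) -> HSBImage:
    """Convert 8-bit RGB to HSB (identical to HSV; pure channel mapping).

    Hue is returned in degrees; achromatic pixels get hue 0 by convention.
    """
    hsv = rgb2hsv(image.pixels)
    return HSBImage(
        hue=hsv[..., 0] * 360.0,
        saturation=hsv[..., 1],
        brightness=hsv[..., 2],
    )


def _brightness_threshold(brightness: np.ndarray, params: SegmentationParams) -> float:
    b = brightness
    if float(b.max()) - float(b.min()) < 1e-9:
        # constant channel: Otsu undefined, fall back to the fixed cut
        return params.brightness_cut
    t = float(threshold_otsu(b, nbins=256))
    lo, hi = params.cut_band
    return min(max(t, lo), hi)


def segment_sky(
    hsb: HSBImage, params: SegmentationParams = DEFAULT_SEGMENTATION
) -> SegmentationMask:
    """Label each pixel sky or vegetation; deterministic given ``params``.

    Degenerate all-one-class images are valid input and produce all-True or
    all-False masks.
    """
    hue, sat, bri = hsb.hue, hsb.saturation, hsb.brightness
    if params.median_prefilter:
        hue = median_filter(hue, size=3)
        sat = median_filter(sat, size=3)
        bri = median_filter(bri, size=3)

    t = _brightness_threshold(bri, params)
    sky = bri > t

    # bright sunlit leaves: saturated green candidates go back to vegetation
    h_lo, h_hi = params.green_hue_band
    sunlit_leaf = sky & (sat > params.green_sat_min) & (hue >= h_lo) & (hue <= h_hi)
    sky &= ~sunlit_leaf
    return SegmentationMask(mask=sky)


def gap_fraction(mask: SegmentationMask) -> GapFractionResult:
    """P0 = n_sky / n_total; flags saturation when no sky pixel was found."""
    if mask.n_total == 0:
        raise ValueError("cannot compute a gap fraction from an empty mask")
    p0 = mask.n_sky / mask.n_total
    return GapFractionResult(p0=p0, saturated=(mask.n_sky == 0), mask=mask)


def gap_fraction_of_image(
    image: CanopyImage, params: SegmentationParams = DEFAULT_SEGMENTATION
) -> GapFractionResult:
    """Full per-image chain: RGB → HSB → sky mask → P0."""
    return gap_fraction(segment_sky(rgb_to_hsb(image), params))


# ---------------------------------------------------------------------------
# I/O helpers


def write_mask_png(mask: SegmentationMask, path: str | Path) -> None:
    """Write the sky mask as an 8-bit PNG (sky = 255, vegetation = 0)."""
    Image.fromarray(mask.mask.astype(np.uint8) * 255, mode="L").save(path)


def write_results_csv(
    rows: Iterable[tuple[str, GapFractionResult]], path: str | Path
) -> None:
    """One CSV row per image: image_path, n_sky, n_total, p0, saturated."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_path", "n_sky", "n_total", "p0", "saturated"])
        for image_path, res in rows:
            w.writerow(
                [image_path, res.mask.n_sky, res.mask.n_total,
                 repr(res.p0), res.saturated]
            )
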