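"""Synthetic below-canopy scenes and NDVI fields with known ground truth.

The canopy renderer uses a Boolean (overlapping-disk) model: opaque leaf
disks of radius r are dropped by a homogeneous Poisson process of intensity
λ = k·LAI/(π·r²) per pixel² over a sky background.  For such a model the
pixel gap probability is exactly exp(−λπr²) = exp(−k·LAI) — the same law
the turbid-medium inversion assumes — so recovering the planted LAI from a
render is an honest end-to-end oracle for the whole segmentation +
inversion chain.

A clumped variant groups the same expected number of disks around Poisson
"shoot" centres.  Overlap within clusters raises the gap fraction above
exp(−k·LAI), so the inversion underestimates truth — the direction real
row canopies err in, with leaves clumped in walls.

Colors are drawn in HSB around a sky palette (bright, weakly saturated
blue) and a leaf palette (dark saturated green) with seeded jitter; all
randomness flows from one explicit seed, never global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk

from .inversion import DEFAULT_MODEL
from .mapping import NdviRaster
from .segmentation import CanopyImage

__all__ = [
    "SceneSpec",
    "render_canopy",
    "make_ndvi_field",
    "generate_fixture_set",
]

# palette centre ± jitter half-width, per HSB channel
SKY_PALETTE = {"hue": (210.0, 12.0), "sat": (0.15, 0.05), "bri": (0.95, 0.03)}
LEAF_PALETTE = {"hue": (120.0, 25.0), "sat": (0.80, 0.10), "bri": (0.35, 0.08)}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene.

    ``k`` is the extinction coefficient used for rendering; it defaults to
    the inversion model's own k so that render → segment → invert is an
    identity in expectation.  ``clumped`` switches to the shoot-cluster
    variant (``cluster_size`` disks per shoot on average, scattered with
    standard deviation ``cluster_sd_px``).
    """

    lai_true: float
    k: float = DEFAULT_MODEL.k
    height: int = 512
    width: int = 512
    leaf_disk_radius_px: int = 12
    seed: int = 0
    clumped: bool = False
    cluster_size: float = 8.0
    cluster_sd_px: float = 18.0

    def __post_init__(self) -> None:
        if self.lai_true < 0:
            raise ValueError("true LAI cannot be negative")
        if self.leaf_disk_radius_px >= min(self.height, self.width):
            raise ValueError("leaf disk radius must be smaller than the image")
        if self.k <= 0:
            raise ValueError("extinction coefficient must be positive")

    @property
    def expected_gap_fraction(self) -> float:
        return math.exp(-self.k * self.lai_true)


def _jitter(rng: np.random.Generator, centre_halfwidth: tuple[float, float], n):
    c, hw = centre_halfwidth
    return c + rng.uniform(-hw, hw, size=n)


def _disk_centres(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Disk centres over the image extended by one radius (edge correction)."""
    r = spec.leaf_disk_radius_px
    h_ext, w_ext = spec.height + 2 * r, spec.width + 2 * r
    lam = spec.k * spec.lai_true / (math.pi * r**2)  # disks per pixel²
    if spec.clumped:
        n_parents = rng.poisson(lam * h_ext * w_ext / spec.cluster_size)
        parents = np.column_stack(
            [rng.uniform(-r, spec.height + r, n_parents),
             rng.uniform(-r, spec.width + r, n_parents)]
        )
        counts = rng.poisson(spec.cluster_size, size=n_parents)
        centres = np.repeat(parents, counts, axis=0)
        centres += rng.normal(0.0, spec.cluster_sd_px, size=centres.shape)
        return centres
    n = rng.poisson(lam * h_ext * w_ext)
    return np.column_stack(
        [rng.uniform(-r, spec.height + r, n), rng.uniform(-r, spec.width + r, n)]
    )


def render_canopy(spec: SceneSpec, return_truth: bool = False):
    """Render one scene; pixel-identical for identical specs (incl. seed).

    With ``return_truth=True`` also returns the ground-truth vegetation
    mask (True where a leaf disk covers the pixel).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    hue = _jitter(rng, SKY_PALETTE["hue"], (h, w))
    sat = _jitter(rng, SKY_PALETTE["sat"], (h, w))
    bri = _jitter(rng, SKY_PALETTE["bri"], (h, w))

    centres = _disk_centres(spec, rng)
    leaf_hue = _jitter(rng, LEAF_PALETTE["hue"], len(centres))
    leaf_sat = _jitter(rng, LEAF_PALETTE["sat"], len(centres))
    leaf_bri = _jitter(rng, LEAF_PALETTE["bri"], len(centres))

    veg = np.zeros((h, w), dtype=bool)
    for (cy, cx), lh, ls, lb in zip(centres, leaf_hue, leaf_sat, leaf_bri):
        rr, cc = draw_disk((cy, cx), spec.leaf_disk_radius_px, shape=(h, w))
        hue[rr, cc] = lh
        sat[rr, cc] = ls
        bri[rr, cc] = lb
        veg[rr, cc] = True

    hsv = np.stack([(hue % 360.0) / 360.0, np.clip(sat, 0, 1), np.clip(bri, 0, 1)],
                   axis=-1)
    rgb = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    image = CanopyImage(pixels=rgb, view_angle_deg=57.5)
    if return_truth:
        return image, veg
    return image


def make_ndvi_field(
    lai_field: np.ndarray,
    a: float,
    b: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> NdviRaster:
    """NDVI grid carrying a known linear LAI relationship lai = a·ndvi + b.

    Cells are ndvi = (lai − b)/a plus seeded Gaussian noise, clipped to the
    valid NDVI range [−1, 1]; NaN (no-data) cells propagate.
    """
    if a == 0:
        raise ValueError("slope a must be non-zero")
    lai = np.asarray(lai_field, dtype=float)
    ndvi = (lai - b) / a
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ndvi = ndvi + rng.normal(0.0, noise_sd, size=ndvi.shape)
    ndvi = np.clip(ndvi, -1.0, 1.0)
    ndvi = np.where(np.isnan(lai), np.nan, ndvi)
    return NdviRaster(grid=ndvi)


def generate_fixture_set(
    outdir: str | Path,
    lai_by_area: dict[str, float],
    n_vines: int = 1,
    seed: int = 0,
    size: tuple[int, int] = (256, 256),
) -> Path:
    """Write a protocol-compatible image set plus manifest CSV.

    For every sampling area a true LAI is given; each vine receives the
    protocol's four replicates (left/right side × 20/40 cm offsets), each
    an independent render at that LAI.  Returns the manifest path.
    """
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    counter = 0
    for area_id, lai_true in sorted(lai_by_area.items()):
        for v in range(n_vines):
            vine_id = f"{area_id}_v{v + 1}"
            for side in ("left", "right"):
                for offset in (20, 40):
                    spec = SceneSpec(
                        lai_true=lai_true, height=size[0], width=size[1],
                        seed=seed + counter,
                    )
                    counter += 1
                    name = f"{vine_id}_{side}_{offset}.png"
                    Image.fromarray(render_canopy(spec).pixels).save(outdir / name)
                    rows.append(
                        {"image_path": name, "vine_id": vine_id,
                         "area_id": area_id, "side": side, "offset_cm": offset}
                    )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
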