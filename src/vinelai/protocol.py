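"""Replicate aggregation and plant↔vineyard LAI scale conversions.

The field protocol takes four below-canopy shots per vine (two row sides ×
offsets of 20 and 40 cm from the pole), each inverted to a plant-scale LAI
(LAIp).  Replicates average to a vine estimate; vines average to a
sampling-area estimate.

LAIp refers leaf area to the ground strip the instrument sees: the vine
spacing V times twice the device-to-row distance D (the device integrates
both sides of the row).  Vineyard LAI (LAIv) refers the same leaf area to
the whole ground area allotted to one vine, R·V with row spacing R:

    LA   = LAIp · 2D · V          (leaf area per plant, m²)
    LAIp = LA / (2D · V)
    LAIv = LAIp · 2D / R

Two named geometries are provided.  ``field_protocol`` is the acquisition
setup (D = 0.4 m, so a 0.8 m reference width; R = 2.4 m, V = 1.0 m).
``paper_discussion`` uses a 1 m² per-plant reference area (reference width
1.0 m, same R and V): the worked high-vigor conversions in the source
study's discussion (LAIv 2.84 ↔ LAIp 6.8; 1.41 ↔ 3.4) are only consistent
with that reference area, not with the 0.8 m protocol width, so both
parameterizations are kept explicit rather than silently reconciled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .inversion import DEFAULT_MODEL, InversionModel, clamp_saturated, lai_from_gap_fraction
from .segmentation import DEFAULT_SEGMENTATION, SegmentationParams, gap_fraction_of_image, load_image

__all__ = [
    "ProtocolGeometry",
    "VineEstimate",
    "AreaEstimate",
    "aggregate_vine",
    "aggregate_area",
    "laip_to_laiv",
    "laiv_to_laip",
    "plant_leaf_area",
    "process_manifest",
]


@dataclass(frozen=True)
class ProtocolGeometry:
    """Device distance D, row spacing R and vine spacing V, all metres."""

    D: float = 0.4
    R: float = 2.4
    V: float = 1.0
    height_below_canopy_cm: float = 15.0  # informational only

    def __post_init__(self) -> None:
        if self.D <= 0 or self.R <= 0 or self.V <= 0:
            raise ValueError("D, R and V must be positive")
        if 2.0 * self.D > self.R:
            raise ValueError(
                f"reference width 2·D = {2 * self.D:g} m exceeds row spacing "
                f"R = {self.R:g} m"
            )

    @property
    def reference_width(self) -> float:
        """Width of the ground strip seen by the device, 2·D (m)."""
        return 2.0 * self.D

    @classmethod
    def field_protocol(cls) -> "ProtocolGeometry":
        """Acquisition geometry: D = 0.4 m, R = 2.4 m, V = 1.0 m."""
        return cls(D=0.4, R=2.4, V=1.0)

    @classmethod
    def paper_discussion(cls) -> "ProtocolGeometry":
        """1 m² per-plant reference area (reference width 1.0 m, R = 2.4, V = 1.0)."""
        return cls(D=0.5, R=2.4, V=1.0)


PRESETS = {
    "field_protocol": ProtocolGeometry.field_protocol,
    "paper_discussion": ProtocolGeometry.paper_discussion,
}


@dataclass
class VineEstimate:
    vine_id: str
    replicates: list[float]
    laip: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.replicates) == 0:
            raise ValueError("a vine estimate needs at least one replicate")
        self.laip = float(np.mean(self.replicates))

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass
class AreaEstimate:
    area_id: str
    vines: list[VineEstimate]
    geometry: ProtocolGeometry
    laip_mean: float = field(init=False)
    laiv: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.vines) == 0:
            raise ValueError("an area estimate needs at least one vine")
        self.laip_mean = float(np.mean([v.laip for v in self.vines]))
        self.laiv = laip_to_laiv(self.laip_mean, self.geometry)


def aggregate_vine(replicates: Sequence[float], vine_id: str = "") -> VineEstimate:
    """Unweighted mean of per-image LAIp replicates; warns off-protocol counts."""
    est = VineEstimate(vine_id=vine_id, replicates=list(replicates))
    if est.n_replicates != 4:
        warnings.warn(
            f"vine {vine_id or '?'}: {est.n_replicates} replicates "
            "(protocol expects 4: 2 sides × 2 offsets)",
            stacklevel=2,
        )
    return est


def aggregate_area(
    vines: Sequence[VineEstimate], geom: ProtocolGeometry, area_id: str = ""
) -> AreaEstimate:
    return AreaEstimate(area_id=area_id, vines=list(vines), geometry=geom)


def laip_to_laiv(laip: float, geom: ProtocolGeometry) -> float:
    """LAIv = LAIp · 2D / R."""
    if laip < 0:
        raise ValueError("plant LAI cannot be negative")
    return laip * geom.reference_width / geom.R


def laiv_to_laip(laiv: float, geom: ProtocolGeometry) -> float:
    """Exact inverse of :func:`laip_to_laiv`: LAIp = LAIv · R / 2D."""
    if laiv < 0:
        raise ValueError("vineyard LAI cannot be negative")
    return laiv * geom.R / geom.reference_width


def plant_leaf_area(laip: float, geom: ProtocolGeometry) -> float:
    """Leaf area per plant LA = LAIp · 2D · V (m²)."""
    if laip < 0:
        raise ValueError("plant LAI cannot be negative")
    return laip * geom.reference_width * geom.V


# ---------------------------------------------------------------------------
# Batch processing of a field-campaign manifest

MANIFEST_COLUMNS = ["image_path", "vine_id", "area_id", "side", "offset_cm"]


def process_manifest(
    manifest: pd.DataFrame | str | Path,
    geom: ProtocolGeometry,
    seg_params: SegmentationParams = DEFAULT_SEGMENTATION,
    model: InversionModel = DEFAULT_MODEL,
    base_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full chain over a manifest CSV.

    The manifest needs columns image_path, vine_id, area_id (side and
    offset_cm are carried through when present).  Relative image paths are
    resolved against ``base_dir`` (defaults to the manifest's directory).
    Returns DataFrames at replicate, vine and area level; an unreadable
    image is recorded as an error row and the run continues.
    """
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if base_dir is None:
            base_dir = path.parent
        manifest = pd.read_csv(path)
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    missing = {"image_path", "vine_id", "area_id"} - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    base = Path(base_dir) if base_dir is not None else Path(".")

    rep_rows = []
    for rec in manifest.to_dict("records"):
        img_path = Path(rec["image_path"])
        if not img_path.is_absolute():
            img_path = base / img_path
        row = {
            "image_path": str(rec["image_path"]),
            "vine_id": str(rec["vine_id"]),
            "area_id": str(rec["area_id"]),
            "side": rec.get("side"),
            "offset_cm": rec.get("offset_cm"),
        }
        try:
            res = gap_fraction_of_image(load_image(img_path), seg_params)
            p0, clamped = clamp_saturated(res.p0, res.mask.n_total)
            row.update(
                p0=res.p0,
                saturated=bool(res.saturated or clamped),
                laip=lai_from_gap_fraction(p0, model),
                error="",
            )
        except (OSError, ValueError) as exc:
            row.update(p0=np.nan, saturated=False, laip=np.nan, error=str(exc))
        rep_rows.append(row)
    replicates = pd.DataFrame(rep_rows)

    vine_rows = []
    ok = replicates[replicates["error"] == ""]
    for (area_id, vine_id), grp in ok.groupby(["area_id", "vine_id"], sort=True):
        est = aggregate_vine(grp["laip"].tolist(), vine_id=vine_id)
        vine_rows.append(
            {"area_id": area_id, "vine_id": vine_id,
             "n_replicates": est.n_replicates, "laip": est.laip}
        )
    vines = pd.DataFrame(vine_rows)

    area_rows = []
    for area_id, grp in vines.groupby("area_id", sort=True):
        ests = [
            VineEstimate(vine_id=r.vine_id, replicates=[r.laip])
            for r in grp.itertuples()
        ]
        area = aggregate_area(ests, geom, area_id=area_id)
        area_rows.append(
            {"area_id": area_id, "n_vines": len(ests),
             "laip_mean": area.laip_mean, "laiv": area.laiv}
        )
    areas = pd.DataFrame(area_rows)
    return {"replicates": replicates, "vines": vines, "areas": areas}
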