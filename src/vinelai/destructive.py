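"""Destructive reference LAI and the theoretical-leaf-number vigor index.

The reference measurement strips every leaf from a sample vine, weighs the
total fresh leaf mass W (g), and converts mass to area through the specific
leaf area (SLA, m² per g fresh weight).  SLA comes from a subsample of
leaf discs of known punch area, weighed jointly:

    SLA  = (n_discs · disc_area) / discs_total_weight
    LAIv = W · SLA / (R · V)

i.e. the per-plant leaf area W·SLA referred to the ground area allotted to
one vine.  The theoretical leaf number TL — shoots per plant × mean leaves
per shoot over a small shoot sample — is a quick non-destructive vigor
descriptor used alongside LAI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .protocol import ProtocolGeometry

__all__ = [
    "DestructiveSample",
    "VigorIndex",
    "specific_leaf_area",
    "destructive_laiv",
    "theoretical_leaf_number",
    "read_destructive_csv",
]


@dataclass(frozen=True)
class DestructiveSample:
    """One vine's destructive record: total fresh weight and the disc subsample.

    Protocol values: 40 discs of 0.01 m² each, punched one per leaf from a
    subsample spanning leaf ages, weighed together.
    """

    vine_id: str
    W: float                  # total leaf fresh weight, g
    discs_total_weight: float  # joint fresh weight of all discs, g
    n_discs: int = 40
    disc_area: float = 0.01   # m² per disc

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("leaf fresh weight must be positive")
        if self.n_discs < 1:
            raise ValueError("need at least one disc")
        if self.discs_total_weight <= 0:
            raise ValueError("disc weight must be positive")
        if self.disc_area <= 0:
            raise ValueError("disc area must be positive")


@dataclass(frozen=True)
class VigorIndex:
    n_shoots: float
    leaves_per_shoot: float

    @property
    def tl(self) -> float:
        return self.n_shoots * self.leaves_per_shoot


def specific_leaf_area(sample: DestructiveSample) -> float:
    """SLA = (n_discs · disc_area) / discs_total_weight, m²·g⁻¹ fresh weight.

    Pooled disc weight, not a per-disc mean of ratios: the discs are weighed
    jointly in the protocol.
    """
    return sample.n_discs * sample.disc_area / sample.discs_total_weight


def destructive_laiv(W: float, sla: float, geom: ProtocolGeometry) -> float:
    """LAIv = W · SLA / (R · V): per-plant leaf area over the per-vine ground area."""
    if W <= 0:
        raise ValueError("leaf fresh weight must be positive")
    if sla <= 0:
        raise ValueError("specific leaf area must be positive")
    return W * sla / (geom.R * geom.V)


def theoretical_leaf_number(n_shoots: float, leaves_per_shoot: float) -> float:
    """TL = shoot count × mean leaves per shoot (mean over a 5-shoot sample)."""
    if n_shoots < 0 or leaves_per_shoot < 0:
        raise ValueError("counts cannot be negative")
    return n_shoots * leaves_per_shoot


def read_destructive_csv(path: str | Path, geom: ProtocolGeometry) -> pd.DataFrame:
    """Load a destructive-sampling table and derive SLA, LAIv and TL per vine.

    Expected columns: vine_id, leaf_fresh_weight_g, n_discs, disc_area_m2,
    discs_weight_g and optionally n_shoots, leaves_per_shoot.
    """
    df = pd.read_csv(path)
    required = {"vine_id", "leaf_fresh_weight_g", "n_discs", "disc_area_m2", "discs_weight_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"destructive table lacks columns: {sorted(missing)}")
    out = df.copy()
    out["sla_m2_per_g"] = df["n_discs"] * df["disc_area_m2"] / df["discs_weight_g"]
    out["laiv"] = [
        destructive_laiv(w, s, geom)
        for w, s in zip(df["leaf_fresh_weight_g"], out["sla_m2_per_g"])
    ]
    if {"n_shoots", "leaves_per_shoot"} <= set(df.columns):
        out["tl"] = df["n_shoots"] * df["leaves_per_shoot"]
    return out
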