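"""Gap-fraction inversion at the 57.5° view angle.

Under the turbid-medium assumption the probability that a view ray misses
all foliage is ``P0 = exp(-k · LAI)`` with extinction coefficient
``k = G(θ) / cos θ``.  At θ = 57.5° the leaf projection function G is very
close to 0.5 for any leaf angle distribution, so a single fixed k inverts
the model without canopy-specific calibration:

    LAI = -ln(P0) / k,   k = 0.5 / cos(57.5°) ≈ 0.9306

LAI obtained this way is on the *plant* scale (LAIp): leaf area referred to
the ground strip the instrument actually sees.  Scale conversions live in
:mod:`vinelai.protocol`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["InversionModel", "DEFAULT_MODEL", "lai_from_gap_fraction", "clamp_saturated"]


@dataclass(frozen=True)
class InversionModel:
    """Extinction model: view zenith angle θ (degrees) and G(θ)."""

    theta_deg: float = 57.5
    g_value: float = 0.5

    @property
    def k(self) -> float:
        """Extinction coefficient G(θ)/cos θ; ≈ 0.9306 with the defaults."""
        k = self.g_value / math.cos(math.radians(self.theta_deg))
        if k <= 0:
            raise ValueError("extinction coefficient must be positive")
        return k


DEFAULT_MODEL = InversionModel()


def lai_from_gap_fraction(p0: float, model: InversionModel = DEFAULT_MODEL) -> float:
    """Invert P0 = exp(-k·LAI); strictly decreasing in p0, LAI(1) = 0.

    Raises for p0 ≤ 0 (a fully closed canopy saturates the method — clamp
    upstream with :func:`clamp_saturated`) and for p0 > 1.
    """
    if not 0.0 < p0 <= 1.0:
        raise ValueError(
            f"gap fraction must lie in (0, 1], got {p0!r}; "
            "p0 = 0 means a saturated (no visible sky) image — apply "
            "clamp_saturated before inverting"
        )
    return -math.log(p0) / model.k + 0.0  # normalize -0.0 at p0 = 1


def clamp_saturated(p0: float, n_total: int) -> tuple[float, bool]:
    """Replace a vanishing gap fraction by half a pixel's worth.

    A fully vegetated frame yields p0 = 0 and an infinite LAI.  The smallest
    resolvable non-zero gap is one pixel, so p0 below 1/(2·n_total) is
    clamped to that half-pixel floor and flagged.  Returns
    ``(p0_clamped, was_clamped)``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    floor = 1.0 / (2.0 * n_total)
    if p0 < floor:
        return floor, True
    return p0, False
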