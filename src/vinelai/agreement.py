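"""Agreement statistics between two LAI series.

Quantifies how well an estimated series tracks a reference series (e.g.
indirect vs destructive vineyard LAI, or LAI vs a vigor index) with the
standard agronomic model-evaluation suite:

    RRMSE = 100 · sqrt(Σ(est−obs)²/n) / mean(obs)    [%; optimum 0]
    MAE   = Σ|est−obs| / n                            [series units; optimum 0]
    EF    = 1 − Σ(est−obs)² / Σ(obs−mean(obs))²       [−∞..1; optimum 1]
    CRM   = (Σobs − Σest) / Σobs                      [optimum 0; positive =
                                                       underestimation]
plus the ordinary least-squares line est = slope·obs + intercept and the
squared Pearson correlation R² with a two-sided significance flag at
α = 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PairedSeries", "AgreementReport", "agreement_metrics", "exclude_outlier"]

ALPHA = 0.001  # significance level of the correlation flag


@dataclass
class PairedSeries:
    """Reference values ``obs`` paired with estimates ``est``."""

    obs: np.ndarray
    est: np.ndarray
    excluded: tuple[int, float, float] | None = None  # (index, obs, est) removed

    def __post_init__(self) -> None:
        self.obs = np.asarray(self.obs, dtype=float)
        self.est = np.asarray(self.est, dtype=float)
        if self.obs.ndim != 1 or self.est.ndim != 1:
            raise ValueError("paired series must be one-dimensional")
        if self.obs.shape != self.est.shape:
            raise ValueError("obs and est must have equal length")
        if self.n < 2:
            raise ValueError("need at least two pairs")

    @property
    def n(self) -> int:
        return self.obs.size


@dataclass(frozen=True)
class AgreementReport:
    rrmse: float      # %
    mae: float        # series units
    ef: float         # ≤ 1
    crm: float
    r2: float         # squared Pearson correlation
    slope: float      # OLS est on obs
    intercept: float
    p_value: float    # two-sided test of zero correlation
    significant: bool  # p < 0.001
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n, "rrmse": self.rrmse, "mae": self.mae, "ef": self.ef,
            "crm": self.crm, "r2": self.r2, "slope": self.slope,
            "intercept": self.intercept, "p_value": self.p_value,
            "significant": self.significant,
        }


def agreement_metrics(series: PairedSeries) -> AgreementReport:
    """Compute the full agreement suite for one method pair.

    R² is the squared Pearson correlation (the regression line is reported
    alongside but not used for R²).  Raises when the reference has zero
    mean (RRMSE/CRM undefined) or zero variance (EF undefined).
    """
    obs, est, n = series.obs, series.est, series.n
    obs_mean = obs.mean()
    if obs_mean == 0:
        raise ValueError("RRMSE and CRM are undefined for a zero-mean reference")
    ss_obs = float(((obs - obs_mean) ** 2).sum())
    if ss_obs == 0:
        raise ValueError("EF is undefined for a constant reference series")

    resid = est - obs
    rmse = float(np.sqrt((resid**2).mean()))
    rrmse = 100.0 * rmse / obs_mean
    mae = float(np.abs(resid).mean())
    ef = 1.0 - float((resid**2).sum()) / ss_obs
    crm = float((obs.sum() - est.sum()) / obs.sum())

    lin = stats.linregress(obs, est)
    r, p = stats.pearsonr(obs, est)
    # identical series are perfectly correlated by definition; avoid the
    # rounding of the correlation routine so the optimum is hit exactly
    r2 = 1.0 if float((resid**2).sum()) == 0.0 else float(r**2)
    return AgreementReport(
        rrmse=rrmse, mae=mae, ef=ef, crm=crm, r2=r2,
        slope=float(lin.slope), intercept=float(lin.intercept),
        p_value=float(p), significant=bool(p < ALPHA), n=n,
    )


def exclude_outlier(series: PairedSeries, index: int) -> PairedSeries:
    """Drop one explicit pair (no automatic detection) and record it.

    Mirrors the practice of re-running the agreement analysis with a known
    anomalous sampling area removed.
    """
    if series.n < 3:
        raise ValueError("cannot exclude from a series of fewer than 3 pairs")
    if not -series.n <= index < series.n:
        raise IndexError(f"index {index} out of range for n = {series.n}")
    idx = index % series.n
    keep = np.ones(series.n, dtype=bool)
    keep[idx] = False
    return PairedSeries(
        obs=series.obs[keep],
        est=series.est[keep],
        excluded=(idx, float(series.obs[idx]), float(series.est[idx])),
    )
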