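"""DDI-ratio computation and acceptance verdicts.

Ratios of a victim drug's exposure metric with vs without perpetrators,
signed percent changes, the two-fold acceptance window on
predicted/observed ratios, and the variability-scaled Guest limits that
tighten toward ±20% as the observed interaction approaches 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention for ratio tables)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def ddi_ratio(value_combo: float, value_alone: float) -> float:
    """Exposure ratio combo/alone (AUC, Cmax or Cmin)."""
    if value_alone <= 0 or value_combo <= 0:
        raise ValueError("exposure values must be positive")
    return value_combo / value_alone


def ratio_boundary_flag(ratio: float, decimals: int = 1, eps: float = 5e-3) -> bool:
    """True when the raw ratio sits at the 0.05 rounding boundary, where the
    reported 1-decimal value is sensitive to upstream rounding."""
    frac = abs(ratio) * 10.0**decimals % 1.0
    return abs(frac - 0.5) < eps


def percent_change(value_alone: float, value_combo: float) -> float:
    """Signed percent change of the combo value relative to alone:
    100*(combo - alone)/alone."""
    if value_alone <= 0:
        raise ValueError("baseline exposure must be positive")
    return 100.0 * (value_combo - value_alone) / value_alone


def twofold_verdict(r_pred: float, r_obs: float) -> bool:
    """Predicted/observed DDI ratio within the inclusive [0.5, 2.0] window."""
    if r_obs <= 0 or r_pred <= 0:
        raise ValueError("ratios must be positive")
    q = r_pred / r_obs
    return 0.5 <= q <= 2.0


def guest_limits(r_obs: float, delta: float = 1.25) -> Tuple[float, float]:
    """Acceptance limits on the predicted DDI ratio given the observed one.

    For R >= 1: L = (delta + 2*(R-1))/R and limits are (R/L, R*L). For
    R < 1 the formula is applied to 1/R and the limits inverted, so the
    window is symmetric under inhibition/induction reciprocity. At R=1 and
    delta=1.25 this gives (0.8, 1.25); delta=2 recovers the two-fold
    window."""
    if r_obs <= 0:
        raise ValueError("observed ratio must be positive")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if r_obs >= 1:
        L = (delta + 2.0 * (r_obs - 1.0)) / r_obs
        return (r_obs / L, r_obs * L)
    lo, hi = guest_limits(1.0 / r_obs, delta)
    return (1.0 / hi, 1.0 / lo)


def guest_verdict(r_pred: float, r_obs: float, delta: float = 1.25) -> bool:
    lo, hi = guest_limits(r_obs, delta)
    return lo <= r_pred <= hi


@dataclass
class DDIResult:
    """One victim × perpetrator-set comparison on a single exposure metric."""

    victim: str
    perpetrators: Tuple[str, ...]
    metric: str  # AUC | Cmax | Cmin
    value_alone: float
    value_combo: float
    r_obs: Optional[float] = None
    delta: float = 1.25
    value_sd: Optional[float] = None
    label: str = ""

    @property
    def r_pred(self) -> float:
        return ddi_ratio(self.value_combo, self.value_alone)

    @property
    def r_pred_reported(self) -> float:
        return round_half_away(self.r_pred, 1)

    @property
    def boundary_flag(self) -> bool:
        return ratio_boundary_flag(self.r_pred)

    @property
    def twofold_pass(self) -> Optional[bool]:
        if self.r_obs is None:
            return None
        return twofold_verdict(self.r_pred, self.r_obs)

    @property
    def guest_pass(self) -> Optional[bool]:
        if self.r_obs is None:
            return None
        return guest_verdict(self.r_pred, self.r_obs, self.delta)


def ddi_report(results: Sequence[DDIResult]) -> pd.DataFrame:
    """Tabular report: one row per victim regimen × perpetrator set with
    the metric, the 1-decimal reported ratio, and verdicts where an
    observed ratio was supplied."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        alone = len(r.perpetrators) == 0
        rows.append(
            {
                "victim": r.victim,
                "perpetrators": " + ".join(r.perpetrators),
                "label": r.label,
                "metric": r.metric,
                "value_alone": r.value_alone,
                "value_combo": r.value_combo,
                "value_sd": r.value_sd,
                "ratio": None if alone else r.r_pred,
                "ratio_reported": None if alone else r.r_pred_reported,
                "boundary_flag": False if alone else r.boundary_flag,
                "r_obs": r.r_obs,
                "twofold_pass": r.twofold_pass,
                "guest_pass": r.guest_pass,
            }
        )
    return pd.DataFrame(rows)
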