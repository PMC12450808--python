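"""Three-state partitioned-survival cost-utility engine.

State occupancy is read directly off the two survival curves at each
cycle boundary:

    p_pfs(t)  = min(S_pfs(t), S_os(t))      (clamped if the extrapolated
    p_pd(t)   = S_os(t) - p_pfs(t)           curves cross)
    p_dead(t) = 1 - S_os(t)

Discounted life years, QALYs and the four cost streams (capped drug,
uncapped drug + other pre-progression, post-progression, terminal) are
accumulated over a monthly cycle grid; integration is trapezoidal by
default (a half-cycle-corrected Riemann sum), with a left-endpoint
option for matching models built without half-cycle correction.
The terminal (end-of-life) cost is applied to the death increment of
each cycle, discounted at the cycle's end time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survfit import ParametricFit, survival_at

__all__ = [
    "ModelConfig",
    "ArmSpec",
    "ArmResult",
    "CEResult",
    "occupancy",
    "run_arm",
    "compute_icer",
]

log = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12.0
DEFAULT_WTP_GRID = tuple(range(50_000, 100_001, 5_000))


@dataclass(frozen=True)
class ModelConfig:
    """Global model settings (times in the units stated per field)."""

    cycle_length_months: float = 1.0
    horizon_years: float = 38.0
    discount_rate_annual: float = 0.02
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    jpy_per_usd: float = 150.0
    #: "trapezoid" (half-cycle equivalent) or "left" (no half-cycle correction)
    integration: str = "trapezoid"
    #: "continuous": d(t) = (1+r)^(-t/12) at every boundary;
    #: "annual": d(t) = (1+r)^(-floor(t/12)), stepwise per model year
    discount_compounding: str = "continuous"

    def __post_init__(self):
        if not 0 <= self.discount_rate_annual < 1:
            raise ValueError("discount rate must be in [0, 1)")
        if self.horizon_years <= 0 or self.cycle_length_months <= 0:
            raise ValueError("horizon and cycle length must be > 0")
        if self.integration not in ("trapezoid", "left"):
            raise ValueError("integration must be 'trapezoid' or 'left'")
        if self.discount_compounding not in ("continuous", "annual"):
            raise ValueError("discount_compounding must be 'continuous' or 'annual'")

    @property
    def horizon_months(self) -> float:
        return self.horizon_years * MONTHS_PER_YEAR


@dataclass(frozen=True)
class ArmSpec:
    """Economic and survival inputs of one treatment arm (costs in USD)."""

    name: str
    os: ParametricFit
    pfs: ParametricFit
    drug_cost_capped: float = 0.0  # per month in PFS, stops at cap_months
    drug_cost_uncapped: float = 0.0  # per month in PFS, whole horizon
    cap_months: float = 24.0  # math.inf disables the cap
    other_prepd_cost: float = 0.0  # per month in PFS
    postpd_cost: float = 0.0  # per month in PD
    terminal_cost: float = 0.0  # one-time, per death
    u_pfs: float = 1.0
    u_pd: float = 1.0

    def __post_init__(self):
        for f in (
            "drug_cost_capped",
            "drug_cost_uncapped",
            "other_prepd_cost",
            "postpd_cost",
            "terminal_cost",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not (0 <= self.u_pfs <= 1 and 0 <= self.u_pd <= 1):
            raise ValueError("utilities must lie in [0, 1]")
        if self.cap_months <= 0:
            raise ValueError("cap_months must be > 0 (use math.inf to disable)")

    def with_(self, **kw) -> "ArmSpec":
        return replace(self, **kw)


@dataclass(frozen=True)
class ArmResult:
    """Discounted decomposition of one arm's outcomes and costs."""

    name: str
    ly: float  # discounted life years
    qaly: float
    mean_pfs: float  # undiscounted restricted mean months in PFS
    mean_post_progression: float  # undiscounted restricted mean months in PD
    ly_pfs: float  # discounted years in PFS
    ly_pd: float  # discounted years in PD
    cost_total: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "ly": self.ly,
            "qaly": self.qaly,
            "mean_pfs": self.mean_pfs,
            "mean_post_progression": self.mean_post_progression,
            "ly_pfs": self.ly_pfs,
            "ly_pd": self.ly_pd,
            "cost_total": self.cost_total,
        }
        d.update({f"cost_{k}": v for k, v in self.cost_breakdown.items()})
        return d


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention vs comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # none | intervention_dominant | intervention_dominated | undefined_ratio


def _cycle_grid(config: ModelConfig) -> np.ndarray:
    h = config.horizon_months
    dt = config.cycle_length_months
    if h < dt:
        raise ValueError("horizon shorter than one cycle")
    n = int(math.floor(h / dt + 1e-9))
    times = np.arange(n + 1, dtype=float) * dt
    if times[-1] < h - 1e-9:
        times = np.append(times, h)
    return times


def _discount_factors(times: np.ndarray, config: ModelConfig) -> np.ndarray:
    r = config.discount_rate_annual
    if r == 0:
        return np.ones_like(times)
    if config.discount_compounding == "continuous":
        return (1.0 + r) ** (-times / MONTHS_PER_YEAR)
    return (1.0 + r) ** (-np.floor(times / MONTHS_PER_YEAR))


def occupancy(os: ParametricFit, pfs: ParametricFit, config: ModelConfig) -> pd.DataFrame:
    """State occupancy at each cycle boundary; rows sum to 1."""
    times = _cycle_grid(config)
    s_os = survival_at(os, times)
    s_pfs = survival_at(pfs, times)
    if np.any(s_pfs > s_os + 1e-12):
        log.info(
            "PFS curve exceeds OS curve at %d of %d boundaries; clamping",
            int((s_pfs > s_os + 1e-12).sum()),
            len(times),
        )
    p_pfs = np.minimum(s_pfs, s_os)
    p_pd = s_os - p_pfs
    p_dead = 1.0 - s_os
    return pd.DataFrame(
        {"time_months": times, "pfs": p_pfs, "pd": p_pd, "dead": p_dead}
    )


def _integrate(y: np.ndarray, times: np.ndarray, rule: str) -> float:
    if rule == "trapezoid":
        return float(np.trapezoid(y, times))
    dt = np.diff(times)
    return float(np.sum(y[:-1] * dt))


def accrue(arm: ArmSpec, occ: pd.DataFrame, config: ModelConfig) -> ArmResult:
    """Accumulate discounted outcomes and costs over a precomputed occupancy."""
    times = occ["time_months"].to_numpy()
    p_pfs = occ["pfs"].to_numpy()
    p_pd = occ["pd"].to_numpy()
    s_os = p_pfs + p_pd
    disc = _discount_factors(times, config)
    rule = config.integration

    ly_pfs = _integrate(p_pfs * disc, times, rule) / MONTHS_PER_YEAR
    ly_pd = _integrate(p_pd * disc, times, rule) / MONTHS_PER_YEAR
    ly = ly_pfs + ly_pd
    qaly = arm.u_pfs * ly_pfs + arm.u_pd * ly_pd

    mean_pfs = _integrate(p_pfs, times, rule)
    mean_pd = _integrate(p_pd, times, rule)

    capped_on = times <= arm.cap_months + 1e-9
    drug = arm.drug_cost_capped * _integrate(
        p_pfs * disc * capped_on, times, rule
    ) + arm.drug_cost_uncapped * _integrate(p_pfs * disc, times, rule)
    other = arm.other_prepd_cost * _integrate(p_pfs * disc, times, rule)
    postpd = arm.postpd_cost * _integrate(p_pd * disc, times, rule)
    deaths = s_os[:-1] - s_os[1:]
    terminal = arm.terminal_cost * float(np.sum(deaths * disc[1:]))

    breakdown = {
        "drug_prepd": drug,
        "other_prepd": other,
        "postpd": postpd,
        "terminal": terminal,
    }
    return ArmResult(
        name=arm.name,
        ly=ly,
        qaly=qaly,
        mean_pfs=mean_pfs,
        mean_post_progression=mean_pd,
        ly_pfs=ly_pfs,
        ly_pd=ly_pd,
        cost_total=float(sum(breakdown.values())),
        cost_breakdown=breakdown,
    )


def run_arm(arm: ArmSpec, config: ModelConfig) -> ArmResult:
    """Run the partitioned-survival model for one arm."""
    occ = occupancy(arm.os, arm.pfs, config)
    return accrue(arm, occ, config)


def compute_icer(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost-effectiveness ratio with dominance labelling.

    A ratio is only reported when both increments share a sign pattern
    that makes it meaningful; dominance (more effect for less cost, or
    vice versa) and a zero QALY increment are labelled instead.
    """
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qaly - comparator.qaly
    if dq == 0:
        return CEResult(dc, dq, None, "undefined_ratio")
    if dc < 0 and dq > 0:
        return CEResult(dc, dq, None, "intervention_dominant")
    if dc > 0 and dq < 0:
        return CEResult(dc, dq, None, "intervention_dominated")
    return CEResult(dc, dq, dc / dq, "none")
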