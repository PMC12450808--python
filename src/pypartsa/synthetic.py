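"""Synthetic two-arm trial data with the structure the analysis assumes.

The published inputs this machinery was designed for (digitized KM
curves, at-risk tables, claims-derived cost summaries) cannot be
redistributed, so the generator emits artifacts with the same statistical
structure: per-subject overall-survival and progression-free-survival
times with PFS <= OS, mixed random + administrative censoring, exact KM
step coordinates, exact number-at-risk tables, and gamma-distributed
per-patient monthly cost samples moment-matched to a mean and 95% CI.

Construction: death times are drawn from ``os_family`` (so the OS
marginal is exact), an independent latent progression time from
``pfs_family``, and the PFS time is their minimum — a PFS event is a
progression or a death, whichever comes first, guaranteeing PFS <= OS
per subject.  One shared censoring time (exponential at ``censor_rate``
truncated at ``admin_censor_time``) applies to both endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .families import get_family
from .kmrecon import DigitizedCurve, PseudoIPD, RiskTable, km_estimate

__all__ = [
    "TrialSimConfig",
    "SimulatedArm",
    "simulate_arm",
    "simulate_cost_samples",
    "gamma_from_ci",
]


@dataclass(frozen=True)
class TrialSimConfig:
    """Configuration of one simulated trial arm (times in months)."""

    n_per_arm: int
    os_family: str
    os_params: dict
    pfs_family: str
    pfs_params: dict
    censor_rate: float = 0.0  # hazard per month of random censoring
    admin_censor_time: float = math.inf
    risk_table_interval: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        if self.risk_table_interval <= 0:
            raise ValueError("risk_table_interval must be > 0")
        get_family(self.os_family).validate(self.os_params)
        get_family(self.pfs_family).validate(self.pfs_params)


@dataclass
class SimulatedArm:
    """Simulated IPD plus the published-style artifacts derived from it."""

    ipd_os: PseudoIPD
    ipd_pfs: PseudoIPD
    curve_os: DigitizedCurve
    curve_pfs: DigitizedCurve
    risk_os: RiskTable
    risk_pfs: RiskTable


def _risk_table(obs: np.ndarray, interval: float) -> RiskTable:
    """True number at risk at multiples of ``interval`` (no rounding noise)."""
    t_max = obs.max()
    times = [0.0]
    k = 1
    while k * interval <= t_max:
        times.append(k * interval)
        k += 1
    times = np.asarray(times)
    n = np.array([(obs >= t).sum() for t in times])
    return RiskTable(times, n)


def simulate_arm(cfg: TrialSimConfig) -> SimulatedArm:
    """Simulate one arm and emit its exact KM curves and risk tables."""
    rng = np.random.default_rng(cfg.seed)
    fam_os = get_family(cfg.os_family)
    fam_pfs = get_family(cfg.pfs_family)

    t_death = fam_os.rvs(cfg.os_params, cfg.n_per_arm, rng)
    t_prog = fam_pfs.rvs(cfg.pfs_params, cfg.n_per_arm, rng)
    t_pfs = np.minimum(t_prog, t_death)

    if cfg.censor_rate > 0:
        c = np.minimum(
            rng.exponential(1.0 / cfg.censor_rate, cfg.n_per_arm), cfg.admin_censor_time
        )
    else:
        c = np.full(cfg.n_per_arm, cfg.admin_censor_time)

    obs_os = np.minimum(t_death, c)
    ev_os = (t_death <= c).astype(int)
    obs_pfs = np.minimum(t_pfs, c)
    ev_pfs = (t_pfs <= c).astype(int)
    if not (np.all(np.isfinite(obs_os)) and np.all(np.isfinite(obs_pfs))):
        raise ValueError(
            "non-finite survival times: the chosen family has a cure fraction "
            "and no finite administrative censoring time was set"
        )

    ipd_os = PseudoIPD(obs_os, ev_os)
    ipd_pfs = PseudoIPD(obs_pfs, ev_pfs)
    return SimulatedArm(
        ipd_os=ipd_os,
        ipd_pfs=ipd_pfs,
        curve_os=km_estimate(ipd_os),
        curve_pfs=km_estimate(ipd_pfs),
        risk_os=_risk_table(obs_os, cfg.risk_table_interval),
        risk_pfs=_risk_table(obs_pfs, cfg.risk_table_interval),
    )


def gamma_from_ci(mean: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Gamma (shape, scale) moment-matched to a mean and normal-approx 95% CI.

    sd = (ci_high - ci_low) / 3.92; shape = (mean/sd)^2; scale = sd^2/mean.
    """
    if not (0 < ci_low < mean < ci_high):
        raise ValueError("require 0 < ci_low < mean < ci_high")
    sd = (ci_high - ci_low) / 3.92
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def simulate_cost_samples(
    mean: float, ci_low: float, ci_high: float, n: int, seed: int = 0
) -> np.ndarray:
    """Draw per-patient monthly cost samples from the moment-matched gamma."""
    shape, scale = gamma_from_ci(mean, ci_low, ci_high)
    rng = np.random.default_rng(seed)
    return rng.gamma(shape, scale, n)
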