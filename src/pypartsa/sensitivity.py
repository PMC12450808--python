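"""Deterministic, scenario and probabilistic sensitivity analyses.

One-way DSA re-runs the model with each parameter at its low/high bound
and ranks ICER spreads (tornado diagram).  Scenario analysis refits a
single parametric family to all four curves and re-runs the model.
PSA is a second-order Monte Carlo: each simulation draws every varied
parameter from its distribution (gamma moment-matched to a 95% CI, or
symmetric triangular at +/-10% with mode at the base case), runs both
arms, and records the incremental cost/QALY pair; the CEAC is the
fraction of draws with positive net monetary benefit at each
willingness-to-pay value.  Survival-parameter uncertainty is excluded
by default (an optional multivariate-normal-on-internal-parameters mode
is provided) since published cost-effectiveness inputs typically state
distributions for costs and utilities only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kmrecon import PseudoIPD
from .partsa import ArmResult, ArmSpec, CEResult, ModelConfig, accrue, compute_icer, occupancy
from .survfit import fit_parametric
from .synthetic import gamma_from_ci

__all__ = [
    "ParamRange",
    "PSADraws",
    "CEModel",
    "one_way_dsa",
    "scenario_families",
    "run_psa",
    "ceac",
    "threshold_price",
]

_ARM_TARGETS = ("intervention", "comparator", "both")
DISTRIBUTIONS = ("gamma_from_ci", "triangular_pm10", "fixed")


@dataclass(frozen=True)
class ParamRange:
    """One varied parameter: a path into the model plus its range/distribution.

    ``name`` is ``"<target>.<field>"`` where target is ``intervention``,
    ``comparator``, ``both`` (both arms) or ``config``, and field is an
    :class:`~pypartsa.partsa.ArmSpec` / :class:`~pypartsa.partsa.ModelConfig`
    field, e.g. ``"intervention.u_pfs"`` or ``"both.postpd_cost"``.
    """

    name: str
    base: float
    low: float
    high: float
    distribution: str = "fixed"

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(f"{self.name}: require low <= base <= high")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"{self.name}: unknown distribution {self.distribution!r}; "
                f"expected one of {DISTRIBUTIONS}"
            )


@dataclass(frozen=True)
class PSADraws:
    """Per-simulation incremental cost and QALY pairs."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int

    @property
    def n_sims(self) -> int:
        return len(self.delta_cost)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sim": np.arange(self.n_sims),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


@dataclass(frozen=True)
class CEModel:
    """A full two-arm cost-effectiveness model: arms plus settings."""

    intervention: ArmSpec
    comparator: ArmSpec
    config: ModelConfig

    def run(self) -> tuple[ArmResult, ArmResult, CEResult]:
        ri = run_arm_cached(self.intervention, self.config)
        rc = run_arm_cached(self.comparator, self.config)
        return ri, rc, compute_icer(ri, rc)

    def icer(self) -> float | None:
        return self.run()[2].icer

    def with_param(self, path: str, value: float) -> "CEModel":
        return _apply(self, path, value)


def run_arm_cached(arm: ArmSpec, config: ModelConfig) -> ArmResult:
    occ = occupancy(arm.os, arm.pfs, config)
    return accrue(arm, occ, config)


def _apply(model: CEModel, path: str, value: float) -> CEModel:
    target, _, fld = path.partition(".")
    if not fld:
        raise ValueError(f"parameter path {path!r} must be '<target>.<field>'")
    if target == "config":
        if not hasattr(model.config, fld):
            raise ValueError(f"unknown model-config field in path {path!r}")
        return replace(model, config=replace(model.config, **{fld: value}))
    if target not in _ARM_TARGETS:
        raise ValueError(
            f"unknown target {target!r} in path {path!r}; "
            f"expected one of {_ARM_TARGETS + ('config',)}"
        )
    if not hasattr(model.intervention, fld):
        raise ValueError(f"unknown arm field in path {path!r}")
    kw = {}
    if target in ("intervention", "both"):
        kw["intervention"] = replace(model.intervention, **{fld: value})
    if target in ("comparator", "both"):
        kw["comparator"] = replace(model.comparator, **{fld: value})
    return replace(model, **kw)


def _icer_value(model: CEModel) -> float:
    """ICER as an extended real for ordering: dominance maps to +/- inf."""
    ce = model.run()[2]
    if ce.dominance == "intervention_dominant":
        return -np.inf
    if ce.dominance == "intervention_dominated":
        return np.inf
    if ce.icer is None:
        return np.nan
    return ce.icer


def one_way_dsa(model: CEModel, ranges: list[ParamRange]) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high, sorted by spread."""
    rows = []
    for r in ranges:
        lo = _icer_value(model.with_param(r.name, r.low))
        hi = _icer_value(model.with_param(r.name, r.high))
        rows.append(
            {
                "parameter": r.name,
                "base": r.base,
                "icer_at_low": lo,
                "icer_at_high": hi,
                "spread": abs(hi - lo),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("spread", ascending=False, kind="stable").reset_index(drop=True)


def scenario_families(
    ipds: dict[str, dict[str, PseudoIPD]],
    families: list[str],
    model: CEModel,
) -> pd.DataFrame:
    """Re-run the model with one parametric family fitted to all four curves.

    ``ipds`` maps arm role ("intervention"/"comparator") to endpoint
    ("os"/"pfs") to the reconstructed IPD.  A family that fails to
    converge on any curve yields a flagged row of NaNs, never a silently
    dropped row.
    """
    rows = []
    for fam in families:
        fits = {}
        ok = True
        for role in ("intervention", "comparator"):
            for ep in ("os", "pfs"):
                f = fit_parametric(ipds[role][ep], fam)
                ok = ok and f.converged
                fits[(role, ep)] = f
        row = {"family": fam, "converged": ok}
        if ok:
            m = replace(
                model,
                intervention=model.intervention.with_(
                    os=fits[("intervention", "os")], pfs=fits[("intervention", "pfs")]
                ),
                comparator=model.comparator.with_(
                    os=fits[("comparator", "os")], pfs=fits[("comparator", "pfs")]
                ),
            )
            ri, rc, ce = m.run()
            row.update(
                {
                    "cost_intervention": ri.cost_total,
                    "ly_intervention": ri.ly,
                    "qaly_intervention": ri.qaly,
                    "cost_comparator": rc.cost_total,
                    "ly_comparator": rc.ly,
                    "qaly_comparator": rc.qaly,
                    "delta_cost": ce.delta_cost,
                    "delta_qaly": ce.delta_qaly,
                    "icer": ce.icer if ce.icer is not None else np.nan,
                    "dominance": ce.dominance,
                }
            )
        else:
            row.update({k: np.nan for k in (
                "cost_intervention", "ly_intervention", "qaly_intervention",
                "cost_comparator", "ly_comparator", "qaly_comparator",
                "delta_cost", "delta_qaly", "icer",
            )})
            row["dominance"] = "not_converged"
        rows.append(row)
    return pd.DataFrame(rows)


def _sample(r: ParamRange, rng: np.random.Generator) -> float:
    if r.distribution == "fixed":
        return r.base
    if r.distribution == "triangular_pm10":
        return float(rng.triangular(0.9 * r.base, r.base, 1.1 * r.base))
    shape, scale = gamma_from_ci(r.base, r.low, r.high)
    return float(rng.gamma(shape, scale))


def run_psa(
    model: CEModel,
    ranges: list[ParamRange],
    n_sims: int = 5000,
    seed: int = 0,
    sample_survival: bool = False,
) -> PSADraws:
    """Second-order Monte Carlo over the parameter distributions.

    With ``sample_survival=True`` the internal (log-scale) survival
    parameters of each fitted curve are additionally drawn from a
    multivariate normal with the fit's observed-information covariance.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    for r in ranges:  # validate all paths up front
        model.with_param(r.name, r.base)
    rng = np.random.default_rng(seed)

    grid_paths = any(
        r.name.startswith("config.") and r.name.split(".", 1)[1] in
        ("cycle_length_months", "horizon_years", "integration")
        for r in ranges
    )
    fixed_occ = not grid_paths and not sample_survival
    occ_i = occupancy(model.intervention.os, model.intervention.pfs, model.config)
    occ_c = occupancy(model.comparator.os, model.comparator.pfs, model.config)

    dc = np.empty(n_sims)
    dq = np.empty(n_sims)
    for s in range(n_sims):
        m = model
        for r in ranges:
            m = m.with_param(r.name, _sample(r, rng))
        if sample_survival:
            m = replace(
                m,
                intervention=m.intervention.with_(
                    os=_draw_fit(m.intervention.os, rng),
                    pfs=_draw_fit(m.intervention.pfs, rng),
                ),
                comparator=m.comparator.with_(
                    os=_draw_fit(m.comparator.os, rng),
                    pfs=_draw_fit(m.comparator.pfs, rng),
                ),
            )
        if fixed_occ:
            ri = accrue(m.intervention, occ_i, m.config)
            rc = accrue(m.comparator, occ_c, m.config)
        else:
            ri = run_arm_cached(m.intervention, m.config)
            rc = run_arm_cached(m.comparator, m.config)
        dc[s] = ri.cost_total - rc.cost_total
        dq[s] = ri.qaly - rc.qaly
    return PSADraws(dc, dq, seed)


def _draw_fit(fit, rng: np.random.Generator):
    from .families import get_family
    from .survfit import make_fit

    if fit.cov_internal is None:
        return fit
    x = rng.multivariate_normal(np.asarray(fit.internal), np.asarray(fit.cov_internal))
    fam = get_family(fit.family)
    return make_fit(fit.family, fam.to_natural(x), n=fit.n)


def ceac(draws: PSADraws, wtp_grid) -> pd.DataFrame:
    """Probability of cost-effectiveness vs willingness-to-pay.

    P(lambda) is the fraction of draws with net monetary benefit
    lambda * dQALY - dCost strictly positive (an NMB of exactly zero
    counts as not cost-effective).
    """
    wtp = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if draws.n_sims == 0:
        raise ValueError("draws must be non-empty")
    prob = [
        float(np.mean(w * draws.delta_qaly - draws.delta_cost > 0)) for w in wtp
    ]
    return pd.DataFrame({"wtp": wtp, "probability": prob})


def threshold_price(
    model: CEModel,
    target_wtp: float,
    price_param: str = "intervention.drug_cost_capped",
    bracket: tuple[float, float] = (0.0, 10_000.0),
    tol_icer: float = 1.0,
    max_iter: int = 200,
) -> float:
    """Price at which the ICER crosses the willingness-to-pay threshold.

    Bisection on the price parameter, relying on the ICER being monotone
    increasing in the price over the bracket; converges when the re-run
    ICER is within ``tol_icer`` USD/QALY of the target.
    """

    def g(price: float) -> float:
        return _icer_value(model.with_param(price_param, price)) - target_wtp

    lo, hi = bracket
    glo, ghi = g(lo), g(hi)
    if not (glo < 0 < ghi):
        raise ValueError(
            f"ICER does not cross the target over the bracket: "
            f"ICER({lo}) = {glo + target_wtp:.2f}, ICER({hi}) = {ghi + target_wtp:.2f}, "
            f"target = {target_wtp}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if abs(gm) < tol_icer:
            return mid
        if gm < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("threshold price bisection did not converge")
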