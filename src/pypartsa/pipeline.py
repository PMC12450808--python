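"""End-to-end study orchestration: reconstruct -> fit -> select -> run ->
sensitivity, driven by a single YAML/JSON study configuration.

The pipeline is a pure function of (config, seed, input files): every
stage writes its artifact under the output directory (reconstructed IPD
and fit reports per curve, base-case table, tornado, scenario table, PSA
draws, CEAC, figures) and the consolidated ``report.json`` contains only
numbers present in those artifacts.

Study configuration layout (YAML)::

    seed: 1
    outdir: results
    model: {cycle_length_months: 1, horizon_years: 38, discount_rate_annual: 0.02}
    adopt_family: loglogistic        # or "auto" (best AIC)
    scenario_families: [exponential, weibull, lognormal, loglogistic, gompertz, gengamma]
    arms:
      intervention:
        name: Pembro+FP
        endpoints:                   # per endpoint: curve+risk files OR a parameter block
          os:  {curve: int_os.csv, risk: int_os_risk.csv}
          pfs: {family: loglogistic, params: {scale: 6.3, shape: 1.7}}
        economics: {drug_cost_capped: 4153.77, cap_months: 24, u_pfs: 0.815, u_pd: 0.577}
      comparator: {...}
    sensitivity_ranges:
      - {name: intervention.u_pfs, base: 0.815, low: 0.7335, high: 0.8965,
         distribution: triangular_pm10}
    psa: {n_sims: 5000}
    threshold: {target_wtp: 100000, bracket: [0, 5000]}
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import matplotlib.pyplot as plt
import numpy as np

from . import io as pio
from .kmrecon import reconstruct_ipd
from .partsa import ArmSpec, ModelConfig
from .plotting import ceac_plot, fit_overlay_plot, psa_scatter_plot, tornado_plot
from .sensitivity import (
    CEModel,
    ParamRange,
    ceac,
    one_way_dsa,
    run_psa,
    scenario_families,
    threshold_price,
)
from .survfit import fit_all, make_fit, select_model

__all__ = ["StudyConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_ARM_ROLES = ("intervention", "comparator")
_ENDPOINTS = ("os", "pfs")


@dataclass(frozen=True)
class StudyConfig:
    """A validated study configuration plus the directory paths resolve against."""

    data: dict
    base_dir: Path

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        return cls(pio.load_yaml(path), path.parent)

    def __post_init__(self):
        arms = self.data.get("arms", {})
        for role in _ARM_ROLES:
            if role not in arms:
                raise ValueError(f"config must define arms.{role}")
            for ep in _ENDPOINTS:
                spec = arms[role].get("endpoints", {}).get(ep)
                if spec is None:
                    raise ValueError(f"arms.{role}.endpoints.{ep} missing")
                has_files = "curve" in spec and "risk" in spec
                has_params = "family" in spec and "params" in spec
                if has_files == has_params:
                    raise ValueError(
                        f"arms.{role}.endpoints.{ep}: give exactly one of "
                        "curve+risk files or family+params"
                    )
                if has_files:
                    for key in ("curve", "risk"):
                        p = self.base_dir / spec[key]
                        if not p.exists():
                            raise FileNotFoundError(f"{role}/{ep}: {p} does not exist")

    def path(self, rel) -> Path:
        return self.base_dir / rel


def _model_config(data: dict) -> ModelConfig:
    kw = dict(data.get("model", {}))
    if "wtp_grid" in kw:
        kw["wtp_grid"] = tuple(float(w) for w in kw["wtp_grid"])
    return ModelConfig(**kw)


def _endpoint_fit(cfg: StudyConfig, role: str, ep: str, adopt: str, outdir: Path):
    """Returns (adopted fit, reconstructed IPD or None)."""
    spec = cfg.data["arms"][role]["endpoints"][ep]
    tag = f"{role}_{ep}"
    if "family" in spec:
        log.info("%s: parameter block (%s); reconstruction and fitting skipped", tag, spec["family"])
        return make_fit(spec["family"], spec["params"]), None

    curve = pio.read_curve_csv(cfg.path(spec["curve"]))
    risk = pio.read_risk_csv(cfg.path(spec["risk"]))
    ipd = reconstruct_ipd(curve, risk, total_events=spec.get("total_events"))
    pio.write_ipd_csv(ipd, outdir / f"ipd_{tag}.csv")

    fits = fit_all(ipd)
    ranked, table = select_model(fits)
    pio.write_fits_json(fits, outdir / f"fits_{tag}.json")
    table.to_csv(outdir / f"selection_{tag}.csv", index=False)
    ax = fit_overlay_plot(curve, fits, horizon_months=float(curve.times[-1] * 2))
    ax.figure.savefig(outdir / f"fit_{tag}.png", dpi=120)
    plt.close(ax.figure)

    if adopt == "auto":
        chosen = ranked[0]
    else:
        by_name = {f.family: f for f in fits if f.converged}
        if adopt not in by_name:
            raise ValueError(f"{tag}: adopted family {adopt!r} did not converge")
        chosen = by_name[adopt]
    log.info("%s: adopted %s (AIC %.1f)", tag, chosen.family, chosen.aic)
    return chosen, ipd


def _arm_spec(cfg: StudyConfig, role: str, fits: dict) -> ArmSpec:
    econ = dict(cfg.data["arms"][role].get("economics", {}))
    if str(econ.get("cap_months", "")).lower() in ("inf", "none", ""):
        econ.pop("cap_months", None)
    elif econ.get("cap_months") is not None:
        econ["cap_months"] = float(econ["cap_months"])
    name = cfg.data["arms"][role].get("name", role)
    return ArmSpec(name=name, os=fits[(role, "os")], pfs=fits[(role, "pfs")], **econ)


def _base_case_table(ri, rc, ce):
    import pandas as pd

    rows = [ri.as_dict(), rc.as_dict()]
    df = pd.DataFrame(rows)
    df["delta_cost"] = [ce.delta_cost, np.nan]
    df["delta_qaly"] = [ce.delta_qaly, np.nan]
    df["icer"] = [ce.icer if ce.icer is not None else np.nan, np.nan]
    df["dominance"] = [ce.dominance, ""]
    return df


def run_pipeline(cfg: StudyConfig) -> dict:
    """Execute every configured stage; returns the consolidated report."""
    data = cfg.data
    seed = int(data.get("seed", 0))
    outdir = cfg.path(data.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    adopt = data.get("adopt_family", "auto")

    config = _model_config(data)
    report: dict = {"seed": seed, "adopt_family": adopt}

    fits: dict = {}
    ipds: dict = {"intervention": {}, "comparator": {}}
    have_all_ipd = True
    for role in _ARM_ROLES:
        for ep in _ENDPOINTS:
            try:
                fit, ipd = _endpoint_fit(cfg, role, ep, adopt, outdir)
            except Exception as err:
                raise RuntimeError(f"stage reconstruct/fit failed for {role}/{ep}: {err}") from err
            fits[(role, ep)] = fit
            if ipd is None:
                have_all_ipd = False
            else:
                ipds[role][ep] = ipd

    model = CEModel(
        intervention=_arm_spec(cfg, "intervention", fits),
        comparator=_arm_spec(cfg, "comparator", fits),
        config=config,
    )

    ri, rc, ce = model.run()
    base_tbl = _base_case_table(ri, rc, ce)
    base_tbl.to_csv(outdir / "base_case.csv", index=False)
    report["base_case"] = {
        "intervention": ri.as_dict(),
        "comparator": rc.as_dict(),
        "delta_cost": ce.delta_cost,
        "delta_qaly": ce.delta_qaly,
        "icer": ce.icer,
        "dominance": ce.dominance,
    }

    ranges = [ParamRange(**r) for r in data.get("sensitivity_ranges", [])]
    if ranges:
        tornado = one_way_dsa(model, ranges)
        tornado.to_csv(outdir / "tornado.csv", index=False)
        if ce.icer is not None:
            ax = tornado_plot(tornado, ce.icer)
            ax.figure.savefig(outdir / "tornado.png", dpi=120)
        plt.close(ax.figure)
        report["dsa"] = tornado.to_dict(orient="records")

    families = data.get("scenario_families", [])
    if families and have_all_ipd:
        scen = scenario_families(ipds, families, model)
        scen.to_csv(outdir / "scenario.csv", index=False)
        report["scenario"] = scen.to_dict(orient="records")
    elif families:
        log.info("scenario analysis skipped: not every endpoint has reconstructed IPD")

    if ranges and data.get("psa"):
        n_sims = int(data["psa"].get("n_sims", 5000))
        draws = run_psa(model, ranges, n_sims=n_sims, seed=seed)
        draws.to_frame().to_csv(outdir / "psa_draws.csv", index=False)
        ceac_tbl = ceac(draws, config.wtp_grid)
        ceac_tbl.to_csv(outdir / "ceac.csv", index=False)
        ax = ceac_plot(ceac_tbl)
        ax.figure.savefig(outdir / "ceac.png", dpi=120)
        plt.close(ax.figure)
        ax = psa_scatter_plot(draws, wtp=max(config.wtp_grid))
        ax.figure.savefig(outdir / "psa_scatter.png", dpi=120)
        plt.close(ax.figure)
        report["psa"] = {
            "n_sims": n_sims,
            "mean_delta_cost": float(np.mean(draws.delta_cost)),
            "mean_delta_qaly": float(np.mean(draws.delta_qaly)),
            "ceac": ceac_tbl.to_dict(orient="records"),
        }

    thr = data.get("threshold")
    if thr:
        try:
            price = threshold_price(
                model,
                target_wtp=float(thr["target_wtp"]),
                price_param=thr.get("price_param", "intervention.drug_cost_capped"),
                bracket=tuple(thr.get("bracket", (0.0, 10_000.0))),
            )
            report["threshold_price"] = price
        except ValueError as err:
            report["threshold_price"] = None
            report["threshold_price_note"] = str(err)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
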