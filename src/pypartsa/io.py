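"""CSV/JSON/YAML readers and writers for the pipeline artifacts.

CSV dialects:
  curve: ``time_months,survival``
  risk:  ``time_months,n_at_risk``
  ipd:   ``time_months,event`` with event in {0, 1}
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .kmrecon import DigitizedCurve, PseudoIPD, RiskTable
from .survfit import ParametricFit

__all__ = [
    "read_curve_csv", "write_curve_csv",
    "read_risk_csv", "write_risk_csv",
    "read_ipd_csv", "write_ipd_csv",
    "write_fits_json", "read_fits_json",
    "load_yaml",
]


def read_curve_csv(path) -> DigitizedCurve:
    df = pd.read_csv(path)
    return DigitizedCurve(df["time_months"].to_numpy(), df["survival"].to_numpy())


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_risk_csv(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(df["time_months"].to_numpy(), df["n_at_risk"].to_numpy())


def write_risk_csv(risk: RiskTable, path) -> None:
    risk.to_frame().to_csv(path, index=False)


def read_ipd_csv(path) -> PseudoIPD:
    df = pd.read_csv(path)
    return PseudoIPD(df["time_months"].to_numpy(), df["event"].to_numpy())


def write_ipd_csv(ipd: PseudoIPD, path) -> None:
    ipd.to_frame().to_csv(path, index=False)


def write_fits_json(fits: list[ParametricFit], path) -> None:
    Path(path).write_text(json.dumps([f.to_dict() for f in fits], indent=2, sort_keys=True))


def read_fits_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
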