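"""Standard figures: tornado diagram, CEAC, PSA scatter, fitted curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["tornado_plot", "ceac_plot", "psa_scatter_plot", "fit_overlay_plot"]


def tornado_plot(tornado: pd.DataFrame, base_icer: float, ax=None):
    """Horizontal-bar tornado: ICER spread per varied parameter."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.45 * len(tornado) + 1.5))
    df = tornado.iloc[::-1]  # largest spread on top
    y = np.arange(len(df))
    lo = np.minimum(df["icer_at_low"], df["icer_at_high"])
    hi = np.maximum(df["icer_at_low"], df["icer_at_high"])
    ax.barh(y, hi - lo, left=lo, color="#4878a8", height=0.6)
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
    ax.set_yticks(y, df["parameter"])
    ax.set_xlabel("ICER (USD per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    ax.figure.tight_layout()
    return ax


def ceac_plot(ceac_table: pd.DataFrame, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_table["wtp"], ceac_table["probability"], marker="o", ms=3)
    ax.set_xlabel("Willingness to pay (USD per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    ax.figure.tight_layout()
    return ax


def psa_scatter_plot(draws, wtp: float | None = None, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(draws.delta_qaly, draws.delta_cost, s=4, alpha=0.3)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        q = np.linspace(*ax.get_xlim(), 10)
        ax.plot(q, wtp * q, "r--", lw=1, label=f"WTP {wtp:,.0f}/QALY")
        ax.legend(fontsize=8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (USD)")
    ax.figure.tight_layout()
    return ax


def fit_overlay_plot(curve, fits, horizon_months: float = 60.0, ax=None):
    """Observed KM step curve with fitted parametric overlays."""
    from .survfit import survival_at

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.step(curve.times, curve.survival, where="post", color="k", lw=1.5, label="KM")
    t = np.linspace(0, horizon_months, 300)
    for f in fits:
        if f.converged:
            ax.plot(t, survival_at(f, t), lw=1, label=f.family)
    ax.set_xlabel("Months")
    ax.set_ylabel("Survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax
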