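"""Fit six parametric survival families and rank them for extrapolation.

Fits exponential, Weibull, log-normal, log-logistic, Gompertz and
generalized-gamma models to a right-censored sample by maximum
likelihood and prints the AIC/BIC ranking with extrapolated survival at
landmark times — the table a modeller inspects (together with the
overlay plot) before adopting a family for the economic model.
"""

from pypartsa import TrialSimConfig, fit_all, restricted_mean, select_model, simulate_arm

arm = simulate_arm(
    TrialSimConfig(
        n_per_arm=500,
        os_family="loglogistic",
        os_params={"scale": 12.0, "shape": 1.6},
        pfs_family="exponential",
        pfs_params={"rate": 0.09},
        censor_rate=0.015,
        admin_censor_time=30.0,
        seed=11,
    )
)

fits = fit_all(arm.ipd_os)
ranked, table = select_model(fits, landmarks=(12.0, 24.0, 60.0, 120.0))
print(table.round(3).to_string(index=False))

best = ranked[0]
print(f"\nbest by AIC: {best.family}  params={ {k: round(v, 3) for k, v in best.params.items()} }")
print(f"restricted mean survival over 38 years: {restricted_mean(best, 456.0):.1f} months")
# AIC ranks in-sample fit; the landmark columns show how differently the
# families extrapolate beyond follow-up — the crux of survival-based
# cost-effectiveness modelling, and why selection stays advisory.
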