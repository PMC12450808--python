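"""Parametric fitting: closed-form oracles, recovery, ranking, extrapolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pypartsa import (
    FAMILY_NAMES,
    PseudoIPD,
    fit_all,
    fit_parametric,
    get_family,
    make_fit,
    restricted_mean,
    select_model,
    survival_at,
)


def _sim_ipd(family, params, n, seed, censor_rate=0.0):
    rng = np.random.default_rng(seed)
    fam = get_family(family)
    t = fam.rvs(params, n, rng)
    if censor_rate > 0:
        c = rng.exponential(1.0 / censor_rate, n)
        return PseudoIPD(np.minimum(t, c), (t <= c).astype(int))
    return PseudoIPD(t, np.ones(n, dtype=int))


class TestFit:
    def test_exponential_mle_is_events_over_total_time(self):
        ipd = PseudoIPD(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, dtype=int))
        fit = fit_parametric(ipd, "exponential")
        assert fit.params["rate"] == pytest.approx(0.4, abs=1e-6)
        assert fit.converged

    def test_loglogistic_parameter_recovery_within_10pct(self):
        ipd = _sim_ipd("loglogistic", {"scale": 10.0, "shape": 2.0}, 2000, seed=5)
        fit = fit_parametric(ipd, "loglogistic")
        assert fit.params["scale"] == pytest.approx(10.0, rel=0.1)
        assert fit.params["shape"] == pytest.approx(2.0, rel=0.1)

    def test_gengamma_nests_weibull(self):
        ipd = _sim_ipd("weibull", {"scale": 12.0, "shape": 1.4}, 800, seed=11)
        fw = fit_parametric(ipd, "weibull")
        fg = fit_parametric(ipd, "gengamma")
        assert fg.loglik >= fw.loglik - 1e-4

    def test_aic_bic_identities(self):
        ipd = _sim_ipd("weibull", {"scale": 12.0, "shape": 1.4}, 300, seed=2, censor_rate=0.02)
        for fit in fit_all(ipd):
            if not fit.converged:
                continue
            k = len(fit.params)
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik, abs=1e-9)
            assert fit.bic == pytest.approx(k * np.log(fit.n) - 2 * fit.loglik, abs=1e-9)

    def test_unknown_family_rejected(self):
        ipd = _sim_ipd("exponential", {"rate": 0.1}, 50, seed=0)
        with pytest.raises(ValueError, match="unknown survival family"):
            fit_parametric(ipd, "spline")

    def test_too_few_events_rejected(self):
        ipd = PseudoIPD(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]))
        with pytest.raises(ValueError, match="at least 2 events"):
            fit_parametric(ipd, "exponential")

    def test_zero_times_are_shifted_not_fatal(self):
        ipd = PseudoIPD(np.array([0.0, 1.0, 2.0, 3.0]), np.ones(4, dtype=int))
        fit = fit_parametric(ipd, "weibull")
        assert fit.converged

    def test_matches_lifelines_on_common_families(self):
        """Independent cross-check: lifelines' fitters reach the same optimum."""
        from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter

        ipd = _sim_ipd("loglogistic", {"scale": 9.0, "shape": 1.6}, 500, 7, censor_rate=0.03)
        pairs = [
            ("weibull", WeibullFitter()),
            ("lognormal", LogNormalFitter()),
            ("loglogistic", LogLogisticFitter()),
        ]
        for family, ll in pairs:
            ours = fit_parametric(ipd, family)
            ll.fit(ipd.times, ipd.events)
            assert ours.loglik == pytest.approx(ll.log_likelihood_, abs=1e-3)


class TestSelect:
    def test_single_fit_ranks_first(self):
        ipd = _sim_ipd("exponential", {"rate": 0.1}, 200, seed=1)
        fit = fit_parametric(ipd, "exponential")
        ranked, table = select_model([fit])
        assert ranked[0].family == "exponential"
        assert len(table) == 1

    def test_true_family_within_2_aic_of_best(self):
        ipd = _sim_ipd("exponential", {"rate": 0.08}, 2000, seed=3)
        ranked, _ = select_model(fit_all(ipd))
        aics = {f.family: f.aic for f in ranked}
        assert aics["exponential"] <= min(aics.values()) + 2.0

    def test_bic_breaks_aic_ties(self):
        from dataclasses import replace

        a = replace(make_fit("exponential", {"rate": 0.1}), loglik=-100.0, aic=50.0, bic=60.0)
        b = replace(
            make_fit("weibull", {"scale": 10.0, "shape": 1.0}), loglik=-100.0, aic=50.0, bic=55.0
        )
        ranked, _ = select_model([a, b])
        assert ranked[0].bic == 55.0

    def test_no_converged_fits_rejected(self):
        bad = make_fit("exponential", {"rate": 0.1})
        bad = type(bad)(**{**bad.__dict__, "converged": False})
        with pytest.raises(ValueError, match="no converged"):
            select_model([bad])


class TestEvaluate:
    def test_exponential_closed_form(self):
        fit = make_fit("exponential", {"rate": 0.05})
        assert survival_at(fit, [12.0])[0] == pytest.approx(np.exp(-0.6), abs=1e-12)

    def test_loglogistic_median_at_scale(self):
        fit = make_fit("loglogistic", {"scale": 10.0, "shape": 2.0})
        assert survival_at(fit, [10.0])[0] == pytest.approx(0.5, abs=1e-12)

    def test_negative_shape_gompertz_plateaus(self):
        fit = make_fit("gompertz", {"shape": -0.05, "rate": 0.02})
        plateau = np.exp(0.02 / -0.05)
        assert survival_at(fit, [1e5])[0] == pytest.approx(plateau, abs=1e-9)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            survival_at(make_fit("exponential", {"rate": 0.1}), [-1.0])

    def test_survival_at_zero_is_one_for_all_families(self):
        params = {
            "exponential": {"rate": 0.1},
            "weibull": {"scale": 10, "shape": 1.5},
            "lognormal": {"mu": 2.0, "sigma": 0.7},
            "loglogistic": {"scale": 10, "shape": 1.5},
            "gompertz": {"shape": 0.05, "rate": 0.02},
            "gengamma": {"mu": 2.0, "sigma": 0.7, "Q": 0.5},
        }
        for fam in FAMILY_NAMES:
            fit = make_fit(fam, params[fam])
            s = survival_at(fit, np.linspace(0, 120, 241))
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12), fam


class TestRestrictedMean:
    def test_exponential_unrestricted_mean(self):
        fit = make_fit("exponential", {"rate": 0.1})
        assert restricted_mean(fit, np.inf) == pytest.approx(10.0, abs=1e-5)

    def test_exponential_truncated_closed_form(self):
        fit = make_fit("exponential", {"rate": 0.1})
        assert restricted_mean(fit, 12.0) == pytest.approx((1 - np.exp(-1.2)) / 0.1, abs=1e-6)

    def test_zero_horizon(self):
        assert restricted_mean(make_fit("exponential", {"rate": 0.1}), 0.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(h1=st.floats(1.0, 100.0), h2=st.floats(1.0, 100.0))
    def test_monotone_in_horizon_and_bounded(self, h1, h2):
        fit = make_fit("loglogistic", {"scale": 8.0, "shape": 1.3})
        lo, hi = sorted([h1, h2])
        rlo, rhi = restricted_mean(fit, lo), restricted_mean(fit, hi)
        assert rlo <= rhi + 1e-9
        assert rhi <= hi + 1e-9
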