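"""DSA / scenario / PSA / CEAC / threshold-price behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pypartsa import (
    ParamRange,
    PSADraws,
    ceac,
    one_way_dsa,
    run_psa,
    scenario_families,
    threshold_price,
)


class TestParamRange:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ParamRange("intervention.u_pfs", 0.8, 0.9, 1.0, "fixed")

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="distribution"):
            ParamRange("intervention.u_pfs", 0.8, 0.7, 0.9, "lognormal")

    def test_unresolvable_path_is_named_in_the_error(self, exp_model):
        with pytest.raises(ValueError, match="nonexistent_field"):
            exp_model.with_param("intervention.nonexistent_field", 1.0)
        with pytest.raises(ValueError, match="armX"):
            exp_model.with_param("armX.u_pfs", 1.0)


class TestDSA:
    def test_zero_width_range_gives_zero_spread_ranked_last(self, exp_model):
        ranges = [
            ParamRange("intervention.u_pfs", 0.815, 0.75, 0.88, "fixed"),
            ParamRange("both.postpd_cost", 1100.0, 1100.0, 1100.0, "fixed"),
        ]
        t = one_way_dsa(exp_model, ranges)
        assert t.iloc[-1]["parameter"] == "both.postpd_cost"
        assert t.iloc[-1]["spread"] == 0.0

    def test_raising_intervention_pfs_utility_lowers_icer(self, exp_model):
        r = ParamRange("intervention.u_pfs", 0.815, 0.75, 0.88, "fixed")
        t = one_way_dsa(exp_model, [r])
        assert t.iloc[0]["icer_at_high"] < t.iloc[0]["icer_at_low"]
        # cross-check against direct recomputation
        direct_hi = exp_model.with_param(r.name, r.high).icer()
        assert t.iloc[0]["icer_at_high"] == pytest.approx(direct_hi)

    def test_raising_comparator_cost_lowers_icer(self, exp_model):
        r = ParamRange("comparator.other_prepd_cost", 1400.0, 1200.0, 1600.0, "fixed")
        t = one_way_dsa(exp_model, [r])
        base_dc = exp_model.run()[2].delta_cost
        hi_dc = exp_model.with_param(r.name, r.high).run()[2].delta_cost
        assert hi_dc < base_dc
        assert t.iloc[0]["icer_at_high"] < t.iloc[0]["icer_at_low"]

    def test_spread_order_invariant_to_input_order(self, exp_model):
        ranges = [
            ParamRange("intervention.u_pfs", 0.815, 0.75, 0.88, "fixed"),
            ParamRange("both.u_pd", 0.577, 0.52, 0.63, "fixed"),
            ParamRange("intervention.drug_cost_capped", 4000.0, 3600.0, 4400.0, "fixed"),
        ]
        a = one_way_dsa(exp_model, ranges)
        b = one_way_dsa(exp_model, ranges[::-1])
        assert a["parameter"].tolist() == b["parameter"].tolist()


class TestScenario:
    def test_single_family_row_matches_direct_refit_run(self, sim_arm_300, exp_model):
        ipds = {
            "intervention": {"os": sim_arm_300.ipd_os, "pfs": sim_arm_300.ipd_pfs},
            "comparator": {"os": sim_arm_300.ipd_os, "pfs": sim_arm_300.ipd_pfs},
        }
        tbl = scenario_families(ipds, ["exponential"], exp_model)
        assert len(tbl) == 1 and bool(tbl.iloc[0]["converged"])
        from pypartsa import fit_parametric
        from dataclasses import replace

        f_os = fit_parametric(sim_arm_300.ipd_os, "exponential")
        f_pfs = fit_parametric(sim_arm_300.ipd_pfs, "exponential")
        m = replace(
            exp_model,
            intervention=exp_model.intervention.with_(os=f_os, pfs=f_pfs),
            comparator=exp_model.comparator.with_(os=f_os, pfs=f_pfs),
        )
        ri, rc, ce = m.run()
        assert tbl.iloc[0]["cost_intervention"] == ri.cost_total
        assert tbl.iloc[0]["delta_qaly"] == ce.delta_qaly

    def test_heavy_tailed_families_give_more_life_years(self, exp_model):
        """Calibrated to the same 12-month survival, log-logistic and log-normal
        carry more tail mass than the exponential, hence more (discounted) LY."""
        from pypartsa import make_fit, run_arm

        from scipy.stats import norm

        s12 = 0.55
        lam = -np.log(s12) / 12.0
        cfg = exp_model.config
        ly_exp = run_arm(
            exp_model.intervention.with_(os=make_fit("exponential", {"rate": lam})), cfg
        ).ly
        calibrated = [
            # S(12) = s12 solved analytically for each family
            ("loglogistic", {"scale": 12.0 * (s12 / (1 - s12)) ** (1 / 1.2), "shape": 1.2}),
            ("lognormal", {"mu": np.log(12.0) - 1.4 * norm.ppf(1 - s12), "sigma": 1.4}),
        ]
        for fam, params in calibrated:
            fit = make_fit(fam, params)
            from pypartsa import survival_at

            assert survival_at(fit, [12.0])[0] == pytest.approx(s12, abs=1e-9)
            ly = run_arm(exp_model.intervention.with_(os=fit), cfg).ly
            assert ly >= ly_exp


class TestPSA:
    def test_all_fixed_reproduces_deterministic_base_case(self, exp_model):
        ranges = [
            ParamRange("intervention.u_pfs", 0.815, 0.75, 0.88, "fixed"),
            ParamRange("both.postpd_cost", 1100.0, 1000.0, 1200.0, "fixed"),
        ]
        draws = run_psa(exp_model, ranges, n_sims=25, seed=4)
        _, _, ce = exp_model.run()
        assert np.allclose(draws.delta_cost, ce.delta_cost, rtol=1e-12)
        assert np.allclose(draws.delta_qaly, ce.delta_qaly, rtol=1e-12)

    def test_same_seed_identical_draws(self, exp_model):
        ranges = [ParamRange("both.postpd_cost", 1100.0, 1050.0, 1150.0, "gamma_from_ci")]
        a = run_psa(exp_model, ranges, n_sims=50, seed=11)
        b = run_psa(exp_model, ranges, n_sims=50, seed=11)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_triangular_sample_mean_is_the_base(self):
        rng = np.random.default_rng(0)
        from pypartsa.sensitivity import _sample

        r = ParamRange("intervention.u_pfs", 0.8, 0.72, 0.88, "triangular_pm10")
        x = np.array([_sample(r, rng) for _ in range(100_000)])
        # symmetric triangular: mean = mode = base
        assert abs(x.mean() - 0.8) < 3 * x.std() / np.sqrt(len(x))

    def test_psa_mean_converges_to_base_case_with_symmetric_draws(self, exp_model):
        ranges = [
            ParamRange("intervention.u_pfs", 0.815, 0.7335, 0.8965, "triangular_pm10"),
            ParamRange("both.postpd_cost", 1100.0, 990.0, 1210.0, "triangular_pm10"),
        ]
        draws = run_psa(exp_model, ranges, n_sims=20_000, seed=8)
        _, _, ce = exp_model.run()
        se_c = draws.delta_cost.std() / np.sqrt(draws.n_sims)
        se_q = draws.delta_qaly.std() / np.sqrt(draws.n_sims)
        assert abs(draws.delta_cost.mean() - ce.delta_cost) < 4 * se_c
        assert abs(draws.delta_qaly.mean() - ce.delta_qaly) < 4 * se_q


class TestCEAC:
    def test_dominant_draws_give_probability_one(self):
        d = PSADraws(np.full(10, -5.0), np.full(10, 0.5), seed=0)
        tbl = ceac(d, [0.0, 50_000.0])
        assert (tbl["probability"] == 1.0).all()

    def test_single_draw_steps_at_its_icer(self):
        d = PSADraws(np.array([100.0]), np.array([1.0]), seed=0)
        tbl = ceac(d, [99.0, 100.0, 101.0])
        assert tbl["probability"].tolist() == [0.0, 0.0, 1.0]  # NMB=0 not cost-effective

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        dc=arrays(float, 200, elements=st.floats(-1e5, 1e5)),
        dq=arrays(float, 200, elements=st.floats(-2.0, 2.0)),
        wtp=st.lists(st.floats(0, 2e5), min_size=1, max_size=5),
    )
    def test_matches_brute_force_nmb_count(self, dc, dq, wtp):
        d = PSADraws(dc, dq, seed=0)
        tbl = ceac(d, wtp)
        for w, p in zip(tbl["wtp"], tbl["probability"]):
            brute = sum(1 for c, q in zip(dc, dq) if w * q - c > 0) / len(dc)
            assert p == brute

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ceac(PSADraws(np.array([1.0]), np.array([1.0]), seed=0), [])

    def test_monotone_in_wtp_when_all_gains_positive(self):
        rng = np.random.default_rng(5)
        d = PSADraws(rng.normal(5e4, 2e4, 500), rng.uniform(0.1, 1.0, 500), seed=0)
        tbl = ceac(d, np.linspace(0, 3e5, 31))
        assert (np.diff(tbl["probability"]) >= 0).all()


class TestThresholdPrice:
    def test_self_consistency_at_returned_price(self, exp_model):
        target = 60_000.0
        p = threshold_price(exp_model, target, bracket=(0.0, 4000.0))
        icer = exp_model.with_param("intervention.drug_cost_capped", p).icer()
        assert abs(icer - target) < 1.0

    def test_icer_strictly_increasing_in_capped_price(self, exp_model):
        prices = [0.0, 1000.0, 2000.0, 4000.0]
        icers = [
            exp_model.with_param("intervention.drug_cost_capped", p).icer() for p in prices
        ]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_no_crossing_reports_both_end_icers(self, exp_model):
        with pytest.raises(ValueError, match="ICER"):
            threshold_price(exp_model, target_wtp=1.0, bracket=(0.0, 4000.0))
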