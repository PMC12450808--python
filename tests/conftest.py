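import numpy as np
import pytest

from pypartsa import (
    ArmSpec,
    CEModel,
    ModelConfig,
    TrialSimConfig,
    make_fit,
    simulate_arm,
)


@pytest.fixture(scope="session")
def sim_arm_300():
    """Moderate-size simulated arm with mixed censoring, reused across tests."""
    cfg = TrialSimConfig(
        n_per_arm=300,
        os_family="loglogistic",
        os_params={"scale": 10.0, "shape": 1.5},
        pfs_family="loglogistic",
        pfs_params={"scale": 6.0, "shape": 1.8},
        censor_rate=0.02,
        admin_censor_time=36.0,
        risk_table_interval=3.0,
        seed=20240229,
    )
    return simulate_arm(cfg)


@pytest.fixture()
def exp_model():
    """Two-arm model with exponential curves: everything has a closed form."""
    config = ModelConfig(horizon_years=10.0, discount_rate_annual=0.02)
    intervention = ArmSpec(
        name="A",
        os=make_fit("exponential", {"rate": 0.05}),
        pfs=make_fit("exponential", {"rate": 0.10}),
        drug_cost_capped=4000.0,
        drug_cost_uncapped=140.0,
        cap_months=24.0,
        other_prepd_cost=2800.0,
        postpd_cost=1100.0,
        terminal_cost=9500.0,
        u_pfs=0.815,
        u_pd=0.577,
    )
    comparator = ArmSpec(
        name="B",
        os=make_fit("exponential", {"rate": 0.08}),
        pfs=make_fit("exponential", {"rate": 0.14}),
        drug_cost_uncapped=140.0,
        cap_months=np.inf,
        other_prepd_cost=1400.0,
        postpd_cost=1100.0,
        terminal_cost=9500.0,
        u_pfs=0.797,
        u_pd=0.577,
    )
    return CEModel(intervention=intervention, comparator=comparator, config=config)
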