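import numpy as np
import pandas as pd
import pytest

from abxbench import SimulationConfig, simulate_cohort, toy_spectrum_table


@pytest.fixture(scope="session")
def spectrum():
    return toy_spectrum_table()


@pytest.fixture(scope="session")
def small_cohort():
    """20 hospitals x ~200 stays, independent intercepts; reused across tests."""
    cfg = SimulationConfig(
        n_hospitals=20,
        mean_stays_per_hospital=200,
        rho=0.0,
        n_comorbidity_vars=3,
        n_procedure_vars=2,
        seed=101,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_stay(rng, scores, n_agents=None):
    """A random PatientStay drawing agents from the synthetic score table."""
    from abxbench import AgentDays, PatientStay

    agents = scores.agents()
    dp = int(rng.integers(1, 15))
    k = int(rng.integers(0, min(6, len(agents)) + 1)) if n_agents is None else n_agents
    chosen = rng.choice(agents, size=k, replace=False)
    ad = [AgentDays(a, int(rng.integers(0, dp + 1))) for a in chosen]
    return PatientStay(
        stay_id=f"S{rng.integers(1e6)}",
        hospital_id="H0",
        unit_id="H0-U0",
        month=1,
        age=70.0,
        sex=0,
        dp=dp,
        agent_days=ad,
    )
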