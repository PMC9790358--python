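import numpy as np
import pytest

from predinfer import (
    AgentProfile,
    CohortSpec,
    ObserverConfig,
    TaskConfig,
    generate_session,
    simulate_agent,
)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def observer_config():
    return ObserverConfig()


@pytest.fixture(scope="session")
def session(task_config):
    return generate_session(task_config, seed=11)


@pytest.fixture(scope="session")
def noiseless_coupled_trials(session):
    """Observer-coupled agent with no motor/report noise on a fixed session."""
    profile = AgentProfile(policy="observer-coupled", base_gain=1.0,
                           motor_noise_sd=0.0, confidence_noise_sd=0.0)
    return simulate_agent(profile, session, seed=5)


@pytest.fixture(scope="session")
def small_cohort_spec():
    return CohortSpec(
        groups={
            "CTL": (6, AgentProfile(policy="observer-coupled", base_gain=0.8)),
            "OCD": (5, AgentProfile(policy="smallPE-boosted", base_gain=0.8,
                                    smallpe_boost=0.6)),
        },
        task=TaskConfig(n_blocks=2, trials_per_block=75),
        medication={"CTL": "none", "OCD": "mixed"},
        seed=21,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
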