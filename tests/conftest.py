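import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from casig import (
    C24_PROFILE,
    COL0_PROFILE,
    Genotype,
    SimulationConfig,
    StimulusCondition,
    rng_for_condition,
    simulate_calcium_trace,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Default design with the between-seedling amplitude jitter switched off."""
    return SimulationConfig(
        profiles={
            Genotype.COL0: dataclasses.replace(COL0_PROFILE, amp_cv=0.0),
            Genotype.C24: dataclasses.replace(C24_PROFILE, amp_cv=0.0),
        },
        seed=1,
    )


@pytest.fixture()
def col0_nacl_trace(noise_free_config):
    """Noise-free col0-like response to 200 mM NaCl."""
    cond = StimulusCondition("nacl", 200.0, "col0_like", 1)
    rng = rng_for_condition(noise_free_config.seed, cond)
    return simulate_calcium_trace(cond, noise_free_config, rng)
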