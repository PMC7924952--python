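import numpy as np
import pytest

from fractrans import (
    CovariateProfile,
    ModelParameters,
    TYPICAL_MAN_RATES,
    TYPICAL_WOMAN_RATES,
)
from fractrans import simulate as sim


@pytest.fixture(scope="session")
def woman_params() -> ModelParameters:
    """Typical-woman reference intensities, no covariate effects."""
    return ModelParameters.from_rates(TYPICAL_WOMAN_RATES)


@pytest.fixture(scope="session")
def man_params() -> ModelParameters:
    return ModelParameters.from_rates(TYPICAL_MAN_RATES)


@pytest.fixture(scope="session")
def typical_woman() -> CovariateProfile:
    return CovariateProfile()


@pytest.fixture(scope="session")
def typical_man() -> CovariateProfile:
    return CovariateProfile(male=True)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject Dubbo-like cohort with exact observation, shared
    across tests that only need plausible event-history data."""
    cfg = sim.default_config(n_women=250, n_men=150)
    baseline = sim.sample_baseline(cfg, 42)
    cohort = sim.simulate_paths(cfg, baseline, 43)
    return cfg, cohort, sim.apply_observation(cohort, "exact")


def random_generator(rng: np.random.Generator) -> np.ndarray:
    """A random valid generator on the allowed-transition pattern."""
    from fractrans import ALLOWED_TRANSITIONS, build_generator

    rates = {key: float(rng.uniform(0.005, 0.4)) for key in ALLOWED_TRANSITIONS}
    params = ModelParameters.from_rates(rates)
    return build_generator(params, CovariateProfile())
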