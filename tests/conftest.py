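import numpy as np
import pytest

from vo2kinetics import (
    BreathNoiseModel,
    KineticParams,
    Protocol,
    generate_breath_series,
    generate_cohort,
)


@pytest.fixture(scope="session")
def protocol():
    return Protocol()


@pytest.fixture(scope="session")
def true_params():
    return KineticParams(a_b=750.0, da=1000.0, tau=30.0, td=15.0)


@pytest.fixture(scope="session")
def noise():
    return BreathNoiseModel()


@pytest.fixture(scope="session")
def noiseless():
    return BreathNoiseModel(sd=0.0)


@pytest.fixture(scope="session")
def noisy_series(true_params, protocol, noise):
    return generate_breath_series(true_params, protocol, noise, seed=2024)


@pytest.fixture(scope="session")
def noiseless_series(true_params, protocol, noiseless):
    return generate_breath_series(true_params, protocol, noiseless, seed=2024)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 4 reps — enough structure for assembly/coverage unit tests."""
    return generate_cohort(3, 4, seed=99)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
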