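import numpy as np
import pytest

from milct import PhantomConfig, generate_cohort, generate_patient


@pytest.fixture(scope="session")
def noiseless_config():
    return PhantomConfig(
        grid_shape=(64, 64, 32),
        spacing=(1.0, 1.0, 2.5),
        organ_radius=18.0,
        tumor_radius=6.0,
        organ_intensity=100.0,
        tumor_intensity=200.0,
        background_intensity=0.0,
        noise_sd=0.0,
        n_cases=3,
        n_controls=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def case_volume(noiseless_config):
    return generate_patient(noiseless_config, label=1, seed=5, patient_id="CASE")


@pytest.fixture(scope="session")
def control_volume(noiseless_config):
    return generate_patient(noiseless_config, label=0, seed=6, patient_id="CTRL")


@pytest.fixture(scope="session")
def small_cohort(noiseless_config):
    return generate_cohort(noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
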