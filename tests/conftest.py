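import pytest

from csfmir.design import build_default_design
from csfmir.effects import build_effect_table
from csfmir.qpcr import quantify
from csfmir.simulate import SimulationParams, simulate_ct_dataset


@pytest.fixture(scope="session")
def design():
    return build_default_design()


@pytest.fixture(scope="session")
def effects():
    return build_effect_table()


@pytest.fixture(scope="session")
def noise_free_params():
    return SimulationParams(
        between_patient_sd=0.0, within_patient_sd=0.0, triplicate_sd=0.0,
        spike_in_sd=0.0, seed=1,
    )


@pytest.fixture(scope="session")
def noise_free_ct(design, effects, noise_free_params):
    return simulate_ct_dataset(design, effects, noise_free_params)


@pytest.fixture(scope="session")
def noise_free_patients(noise_free_ct):
    return quantify(noise_free_ct)


@pytest.fixture(scope="session")
def seeded_ct(design, effects):
    """Default-noise cohort at the study group sizes, seed 42."""
    return simulate_ct_dataset(design, effects, SimulationParams(seed=42))


@pytest.fixture(scope="session")
def seeded_patients(seeded_ct):
    return quantify(seeded_ct)
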