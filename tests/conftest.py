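import dataclasses

import pytest

from patterngrid import synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One default 27-patient cohort, shared across tests."""
    return synthetic.generate_cohort(default_config)


@pytest.fixture(scope="session")
def quiet_config():
    """Noiseless, non-switching configuration: every session identical."""
    return dataclasses.replace(
        synthetic.SyntheticConfig(seed=0),
        switch_rate1_range=(0.0, 0.0),
        switch_rate2_range=(0.0, 0.0),
        emission_sd=0.0,
        coder_noise_sd=0.0,
        proc_emission_sd=0.0,
        proc_phase1_sd=0.0,
        proc_peak_sd=0.0,
        tape_missing_prob=0.0,
    )
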