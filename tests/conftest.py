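import pytest

import hwpflow as hf


@pytest.fixture(scope="session")
def params():
    """Synthetic parameter registry shared across the suite."""
    return hf.generate_fixture_set(1)


@pytest.fixture(scope="session")
def bau_harvest_input():
    return hf.HarvestInput(0, "log_type", hf.bau_harvest())


@pytest.fixture(scope="session")
def bau_trajectory(params, bau_harvest_input):
    """One full 120-year BAU run, reused by several modules."""
    return hf.simulate(bau_harvest_input, params, horizon=120)
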