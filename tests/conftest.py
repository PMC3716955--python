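import pytest

import phyloarray as pa


@pytest.fixture(scope="session")
def template():
    return pa.load_reference_community()


@pytest.fixture(scope="session")
def null_cohort(template):
    """9 HC + 10 CD drawn from a shared template: no group effect."""
    config = pa.SimulationConfig(seed=7)
    abund, meta = pa.simulate_abundances(template, config)
    return abund, meta, config


@pytest.fixture(scope="session")
def planted_cohort(template):
    """Same split with the 8-group sub-profile planted at 4-fold."""
    config = pa.SimulationConfig(seed=7, effect_multiplier=4.0)
    abund, meta = pa.simulate_abundances(template, config)
    return abund, meta, config
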