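import pytest

import metpbpk as m


@pytest.fixture(scope="session")
def phys():
    return m.default_physiology()


@pytest.fixture(scope="session")
def geom():
    return m.default_geometry()


@pytest.fixture(scope="session")
def metformin(phys):
    return m.load_drug("metformin", phys)


@pytest.fixture(scope="session")
def cimetidine(phys):
    return m.load_drug("cimetidine", phys)


@pytest.fixture(scope="session")
def fast_options():
    """Looser solver settings for unit tests that only need ~4 digits."""
    return m.SolverOptions(rtol=1e-6, atol=1e-8, grid_step_min=5.0)
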