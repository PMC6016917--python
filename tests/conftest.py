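import pytest

from coferm import SimOptions, default_coculture, ej2_kinetics, sr8_kinetics


@pytest.fixture(scope="session")
def ej2():
    return ej2_kinetics()


@pytest.fixture(scope="session")
def sr8():
    return sr8_kinetics()


@pytest.fixture(scope="session")
def coculture():
    return default_coculture()


@pytest.fixture(scope="session")
def fast_opts():
    """Mildly relaxed tolerances for tests that only need qualitative shape."""
    return SimOptions(rtol=1e-7, atol=1e-9)
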