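import numpy as np
import pytest

from qsn.presets_io import load_preset


@pytest.fixture(scope="session")
def class1():
    return load_preset("dssn_class1")


@pytest.fixture(scope="session")
def class2():
    return load_preset("dssn_class2")


@pytest.fixture(scope="session")
def square_wave():
    return load_preset("analog_square_wave")


@pytest.fixture(scope="session")
def analog_class1():
    return load_preset("analog_class1")


@pytest.fixture(scope="session")
def ulp_class2():
    return load_preset("ulp_class2")


@pytest.fixture(scope="session")
def stored_patterns():
    from qsn.patterns import generate_patterns
    return generate_patterns(256, 4, seed=2024)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
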