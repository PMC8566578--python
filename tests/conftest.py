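import numpy as np
import pytest

from memstack import MATERIALS, NoiseModel, canonical_fixtures, synth_reflectivity


@pytest.fixture(scope="session")
def fixtures():
    return canonical_fixtures()


@pytest.fixture(scope="session")
def ternary(fixtures):
    return fixtures["ternary"]


@pytest.fixture(scope="session")
def binary(fixtures):
    return fixtures["binary"]


@pytest.fixture(scope="session")
def q_grid():
    return np.geomspace(0.005, 0.25, 120)


@pytest.fixture(scope="session")
def ternary_data(ternary):
    """Three-contrast synthetic dataset from the ternary membrane, 3% noise."""
    return synth_reflectivity(
        ternary.stack,
        ("h2o", "d2o", "4mw"),
        noise=NoiseModel(floor=0.03, seed=1),
        name="ternary",
    )


@pytest.fixture(scope="session")
def binary_data(binary):
    """Two-contrast synthetic dataset from the binary membrane, 3% noise."""
    return synth_reflectivity(
        binary.stack,
        ("h2o", "d2o"),
        noise=NoiseModel(floor=0.03, seed=2),
        name="binary",
    )


@pytest.fixture(scope="session")
def si():
    return MATERIALS["silicon"]


@pytest.fixture(scope="session")
def d2o():
    return MATERIALS["d2o"]


@pytest.fixture(scope="session")
def h2o():
    return MATERIALS["h2o"]
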