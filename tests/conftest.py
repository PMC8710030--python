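import numpy as np
import pytest

from torscan.fixtures import amino_backbone_zmatrix, generate_fixture
from torscan.geom import parse_zmatrix

CHAIN_K2 = """\
C
C 1 1.52
C 2 1.52 1 132.0
C 3 1.52 2 132.0 1 t1
C 4 1.52 3 132.0 2 t2

t1 60.0 *
t2 60.0 *
"""


@pytest.fixture
def chain_zmat():
    return parse_zmatrix(CHAIN_K2)


@pytest.fixture
def amino_zmat():
    return amino_backbone_zmatrix()


@pytest.fixture(scope="session")
def separable_fixture():
    return generate_fixture("separable-3fold", 2, 0)


@pytest.fixture(scope="session")
def cs_fixture():
    return generate_fixture("cs-symmetric", 2, 0)


@pytest.fixture(scope="session")
def amino_fixture():
    return generate_fixture("amino-backbone-toy", 3, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
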