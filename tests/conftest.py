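import numpy as np
import pytest

from chlamysec.cleavage_grammar import MotifConfig

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def config():
    return MotifConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20180901)


def random_protein(rng, length, alphabet=AA20):
    return "".join(rng.choice(list(alphabet), size=length))
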