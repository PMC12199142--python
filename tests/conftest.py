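import random

import pytest

from rnalsc.energies import load_turner_params


@pytest.fixture(scope="session")
def params():
    return load_turner_params()


@pytest.fixture()
def rng():
    return random.Random(1234)
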