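import numpy as np
import pytest

from cnidomir.core_io import GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture
def small_background():
    return GeneSet(name="bg", members=frozenset(f"g{i:03d}" for i in range(200)))
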