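import numpy as np
import pytest

from rewireprio.simulate import SyntheticDesign, generate, tiny_fixture


@pytest.fixture
def tiny():
    """Deterministic 6-gene x 8-sample hand-checkable dataset."""
    return tiny_fixture()


@pytest.fixture
def small_dataset():
    """Default synthetic design, fixed seed."""
    return generate(SyntheticDesign(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
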