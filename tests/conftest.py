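import numpy as np
import pytest

from nodulefusion.core_io import NoduleCase
from nodulefusion.synthetic import PhantomConfig, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_case():
    """A deterministic hand-built 16-slice case with a bright square nodule."""
    stack = np.zeros((16, 64, 64))
    stack[6:11, 24:36, 28:40] = 0.8
    return NoduleCase(
        case_id="toy", slices=stack, rect=(24, 28, 35, 39), center_slice=8, label=1
    )


@pytest.fixture
def phantom_case(rng):
    return generate_case(1, PhantomConfig(seed=0), rng, case_id="phantom")
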