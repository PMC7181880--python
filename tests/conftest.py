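import numpy as np
import pytest

from allorecall import CONDITION_NAMES, make_condition


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(params=CONDITION_NAMES)
def condition(request):
    """Each of the four experimental conditions in turn."""
    return make_condition(request.param)


@pytest.fixture
def layout():
    return make_condition("beacon_normal").layout
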