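import numpy as np
import pytest

from tcstune import tcs_model as m


@pytest.fixture(scope="session")
def params():
    return m.default_parameters()


@pytest.fixture(scope="session")
def promoter():
    return m.default_promoter()


@pytest.fixture(scope="session")
def wide_grid(params):
    """Input grid spanning 8 decades around k_input_half (plus zero), wide
    enough to bracket thresholds shifted by extreme activity scales."""
    k = params.k_input_half
    return np.concatenate([[0.0], np.logspace(np.log10(k) - 4, np.log10(k) + 4, 65)])
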