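import numpy as np
import pytest

from fgl.mackey_glass import MGParams, integrate_mg


@pytest.fixture(scope="session")
def chaotic_series():
    """Standard chaotic-regime trajectory shared across tests."""
    return integrate_mg(MGParams(), 3000, seed=1)


@pytest.fixture(scope="session")
def short_series():
    """Shorter trajectory for fast training tests."""
    return integrate_mg(MGParams(washout=200), 800, seed=3)
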