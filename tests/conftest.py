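import numpy as np
import pytest

from neqadapt import (
    SensoryParams,
    ThreeStateParams,
    validate_generator,
)


@pytest.fixture
def two_state_Q():
    return validate_generator([[-1.0, 1.0], [2.0, -2.0]])


@pytest.fixture
def cycle_fixture_params():
    """Three-state cycle with uneven stationary weights and edge sums.

    Feasible flux range [0, 0.2]; the oscillation-onset flux (~0.917) lies
    beyond it, so every feasible response has a real spectrum.
    """
    return ThreeStateParams(np.array([0.1, 0.5, 0.4]), 1.2, 0.6, 0.2, 0.0)


@pytest.fixture
def cycle_fixture_pi_g():
    return np.array([1.0, 0.0, 0.0]), np.array([0.0, 2.0, 1.0])


@pytest.fixture
def mcp_defaults():
    """Standard chemoreceptor constants; ligand step 10*Ki -> 15*Ki."""
    p = SensoryParams()
    return p, 10 * p.Ki, 15 * p.Ki
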