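import numpy as np
import pytest

from switchcycle.modelzoo import SomaticParams
from switchcycle.switchcore import ScalingFunction, SwitchModule


@pytest.fixture(scope="session")
def cubic5_module():
    """S-shaped switch at the standard bend (alpha = 5, r = 0.5, n = 15)."""
    return SwitchModule(K=20.0, n=15.0, xi=ScalingFunction(alpha=5.0))


@pytest.fixture(scope="session")
def nondim_cubic5():
    return SwitchModule(K=1.0, n=15.0, xi=ScalingFunction(alpha=5.0))


@pytest.fixture(scope="session")
def somatic_defaults():
    return SomaticParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
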