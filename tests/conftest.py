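import numpy as np
import pytest

from modincidence import HomogenizedParams, TransitionScenario


@pytest.fixture(scope="session")
def params_cd():
    """Reference homogenized parameters for the post-transition era."""
    return HomogenizedParams(N=12, tau=8.0, T=1240.0, Phi=0.63)


@pytest.fixture(scope="session")
def scenario_outbreak(params_cd):
    """Environmental-transition scenario with the outbreak-era parameters."""
    return TransitionScenario(
        base=params_cd.replace(Phi=0.51), phi_after=0.63, T_star=350.0
    )


@pytest.fixture(scope="session")
def age_grid():
    return np.arange(0.0, 91.0)
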