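import numpy as np
import pytest

from cecox import CopulaSpec, solve_design

LOG08 = np.log(0.8)


@pytest.fixture(scope="session")
def clayton04():
    return CopulaSpec.from_tau("clayton", 0.4)


@pytest.fixture(scope="session")
def independence():
    return CopulaSpec.from_theta("independence")


@pytest.fixture(scope="session")
def clayton_common(clayton04):
    """Clayton tau=0.4, common effects log 0.8, p1=0.25, pi_A=pi=0.2."""
    return solve_design(clayton04, LOG08, LOG08, 0.25, 0.2, 0.2)


@pytest.fixture(scope="session")
def clayton_diff(clayton04):
    """Clayton tau=0.4, beta1=log 0.8, beta2=0, p1=0.25, pi_A=pi=0.2."""
    return solve_design(clayton04, LOG08, 0.0, 0.25, 0.2, 0.2)


@pytest.fixture(scope="session")
def indep_common(independence):
    return solve_design(independence, LOG08, LOG08, 0.25, 0.2, 0.2)


@pytest.fixture(scope="session")
def indep_diff(independence):
    return solve_design(independence, LOG08, 0.0, 0.25, 0.2, 0.2)
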