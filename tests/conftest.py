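import numpy as np
import pytest

from bdan.bath import AnalyticBathSpec, analytic_distribution, debye_grid
from bdan.constants import HBAR_EV_FS
from bdan.synthetic import bd_an_parameter_set


@pytest.fixture(scope="session")
def params():
    return bd_an_parameter_set()


@pytest.fixture(scope="session")
def debye_density():
    """Debye bath with tau_D = 20 fs, lam = 0.24 eV, on a resolving grid."""
    wd = HBAR_EV_FS / 20.0
    return analytic_distribution(
        AnalyticBathSpec("debye", lam=0.24, omega_D=wd), debye_grid(wd, 3.0, 8192)
    )


@pytest.fixture(scope="session")
def composite_density():
    """Half outer-sphere Debye, half 1500 cm^-1 Brownian oscillator."""
    from bdan.constants import cm1_to_ev

    bo = AnalyticBathSpec(
        "brownian_oscillator", lam=0.2415, Omega=cm1_to_ev(1500.0), gamma=0.004
    )
    de = AnalyticBathSpec("debye", lam=0.2415, omega_D=0.002)
    return analytic_distribution([de, bo], debye_grid(0.002, 0.6, 8000))
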