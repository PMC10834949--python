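import numpy as np
import pytest

from fibrilbind.spr import TwoPhaseKineticParams


@pytest.fixture
def demo_kinetics() -> TwoPhaseKineticParams:
    """Ground-truth kinetics for synthetic series: strong site K_D = 12.9 nM
    (k_off2/k_on1 under the crossed pairing), weak site K_D = 10 uM."""
    return TwoPhaseKineticParams(
        k_on1=1.0e5, k_on2=1.0e3, k_off1=1.0e-2, k_off2=1.29e-3,
        B_max1=100.0, B_max2=80.0, a=0.4, t_0=300.0,
    )


@pytest.fixture
def conc_series():
    """Nine two-fold dilutions from 50 uM down to 0.195 uM."""
    return [50e-6 / 2**k for k in range(9)]


@pytest.fixture
def t_grid():
    """0-900 s trace sampling both phases around the 300 s injection stop."""
    return np.arange(0.0, 900.0, 2.0)
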