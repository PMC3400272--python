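import numpy as np
import pytest
import sympy as sp

from crnred.fixtures import build_michaelis_menten


@pytest.fixture
def mm_symbols():
    return sp.symbols("k1 km1 k2 Etot Stot")


@pytest.fixture
def mm_qss_net():
    """Enzyme-dilute regime with k2 >> k-1: the complex is a QSS species."""
    return build_michaelis_menten(10.0, 0.01, 1.0, Etot=0.01, Stot=1.0)


@pytest.fixture
def mm_qe_net():
    """Fast reversible binding with slow catalysis: QE regime."""
    return build_michaelis_menten(10.0, 1.0, 0.001, Etot=0.01, Stot=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
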