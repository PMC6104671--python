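import numpy as np
import pytest

from xslsim import Population, make_tridiagonal


@pytest.fixture
def tri10():
    """The 10-word tri-diagonal adult lexicon."""
    return make_tridiagonal(10)


@pytest.fixture
def pop10(tri10):
    """Single-adult population (no between-speaker diversity)."""
    return Population((tri10,))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
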