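import numpy as np
import pytest

from bregnmf import MaskedMatrix, SolverConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_masked(rng):
    """6x5 positive matrix with a couple of unobserved entries."""
    values = rng.random((6, 5)) * 2 + 0.1
    observed = np.ones((6, 5), dtype=bool)
    observed[0, 3] = False
    observed[4, 1] = False
    return MaskedMatrix(values=values, observed=observed)


@pytest.fixture
def default_config():
    return SolverConfig(rank=2, seed=0)


def brute_force_scalar_min(objective, lo=-20.0, hi=20.0, n=400001):
    """Dense-grid minimizer used as an independent oracle for closed forms."""
    xs = np.linspace(lo, hi, n)
    vals = objective(xs)
    return float(xs[np.argmin(vals)])
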