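import numpy as np
import pytest

from mdqr import (ModelParams, QuantileModelSpec, build_block_weights,
                  generate_panel, make_instruments)


class DegenerateErrors:
    """Error law that always draws a constant (default 0); ppf is 0."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def rvs(self, size, rng):
        return np.full(size, self.value)

    def ppf(self, q):
        return 0.0


class RecordingNormalErrors:
    """Standard normal errors that remember the draws they produced."""

    def __init__(self):
        self.draws = []

    def rvs(self, size, rng):
        out = rng.standard_normal(size)
        self.draws.append(out)
        return out

    def ppf(self, q):
        from scipy.stats import norm

        return float(norm.ppf(q))


@pytest.fixture(scope="session")
def w20():
    return build_block_weights(20)


@pytest.fixture(scope="session")
def w50():
    return build_block_weights(50)


@pytest.fixture(scope="session")
def small_spec():
    """Coarse grid spec for fast estimator tests."""
    return QuantileModelSpec(tau=0.5, rho_grid=np.arange(-0.9, 0.95, 0.1))


@pytest.fixture(scope="session")
def sim_panel(w20):
    """One simulated homoscedastic panel, N=20, T=60, with instruments."""
    rng = np.random.default_rng(42)
    params = ModelParams(rho=0.5, beta=np.array([1.0]),
                         eta=rng.standard_normal(20))
    panel = generate_panel(params, w20, 60, 0.5, "homoscedastic", seed=rng)
    instruments = make_instruments(panel, w20, "spatial_lag_X")
    return panel, instruments
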