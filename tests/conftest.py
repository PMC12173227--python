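import numpy as np
import pytest

from neqbrain.core import CouplingMatrix, SignalPanel
from neqbrain.hopf import HopfParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uncoupled_pair():
    """Two independent nodes (G=0): per-node closed forms apply exactly."""
    mask = np.zeros((2, 2), dtype=bool)
    C = CouplingMatrix(weights=np.zeros((2, 2)), mask=mask)

    def make(a=-0.2, omega=0.3, beta=0.02, seed=0, tr=1.0, dt=0.1, burn_in=200.0):
        return HopfParams(
            a=a, omega=omega, C=C, G=0.0, beta=beta, dt=dt, tr=tr,
            burn_in=burn_in, seed=seed,
        )

    return make


def random_coupling(n, density, rng, scale=0.05, asym=0.0):
    """Random masked coupling; ``asym`` in [0, 1] splits pair weights."""
    upper = np.triu(rng.random((n, n)) < density, k=1)
    mask = upper | upper.T
    iu, ju = np.where(upper)
    w = rng.uniform(0.5, 1.0, iu.size) * scale
    u = rng.uniform(0.0, 1.0, iu.size)
    weights = np.zeros((n, n))
    weights[iu, ju] = w * (1 + asym * u)
    weights[ju, iu] = w * (1 - asym * u)
    return CouplingMatrix(weights=weights, mask=mask)


@pytest.fixture
def coupling_factory(rng):
    return lambda n=5, density=0.6, scale=0.05, asym=0.0: random_coupling(
        n, density, rng, scale=scale, asym=asym
    )


@pytest.fixture
def noise_panel(rng):
    """White-noise panel factory (no temporal structure, reversible)."""

    def make(n=2, t=10_000, tr=2.0):
        return SignalPanel(values=rng.standard_normal((n, t)), tr=tr)

    return make
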