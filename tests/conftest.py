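import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20210331)


@pytest.fixture
def correlated_pair(rng):
    """A clean bivariate normal sample at rho = 0.7, n = 60."""
    cov = [[1.0, 0.7], [0.7, 1.0]]
    z = rng.multivariate_normal([0, 0], cov, size=60)
    return z[:, 0], z[:, 1]
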