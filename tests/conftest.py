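import numpy as np
import pytest
from scipy.special import expit

from ordmap.data import OrdinalDataset


def draw_ordinal(theta, tau_list, rng):
    """Multinomial ordinal draws through the cumulative-logistic link."""
    n, r = theta.shape
    y = np.empty((n, r), dtype=np.int64)
    for j, t in enumerate(tau_list):
        lam = expit(t[None, :] - theta[:, j][:, None])
        y[:, j] = 1 + (rng.random((n, 1)) > lam).sum(axis=1)
    return y


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_dominance(rng):
    """40 x 3 dataset generated from a rank-2 inner-product structure."""
    n, r, s = 40, 3, 2
    u = rng.normal(0, 1, (n, s))
    v = rng.normal(0, 0.8, (r, s))
    theta = u @ v.T
    tau = [np.array([-1.0, 1.0])] * r
    y = draw_ordinal(theta, tau, rng)
    return OrdinalDataset(y, [3] * r), theta


@pytest.fixture
def small_proximity(rng):
    """40 x 3 dataset generated from a distance (unfolding) structure."""
    n, r, s = 40, 3, 2
    u = rng.normal(0, 1, (n, s))
    v = rng.normal(0, 1, (r, s))
    theta = -np.linalg.norm(u[:, None, :] - v[None, :, :], axis=2)
    tau = [np.array([-2.0, -1.0])] * r
    y = draw_ordinal(theta, tau, rng)
    return OrdinalDataset(y, [3] * r), theta
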