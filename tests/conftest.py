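import numpy as np
import pytest

from hetasym import connectome as cn
from hetasym import dynamics as dy


@pytest.fixture(scope="session")
def conn29():
    """Macaque-like synthetic connectome at the standard size/density/asymmetry."""
    return cn.generate_synthetic_connectome(n=29, density=0.65, target_eta=0.7, seed=1)


@pytest.fixture(scope="session")
def conn10():
    """Small connectome for fast end-to-end tests."""
    return cn.generate_synthetic_connectome(n=10, density=0.8, target_eta=0.7, seed=2)


@pytest.fixture(scope="session")
def modelA_gt(conn29):
    """Default Model A at G = 0.8 with its exact ground truth."""
    params = dy.default_modelA(conn29, G=0.8)
    return params, dy.ground_truth(params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def finite_difference_jacobian(params, S_star, eps=1e-6):
    """Central-difference Jacobian of the drift: the shared numerical oracle."""
    m = S_star.size
    J = np.empty((m, m))
    for j in range(m):
        e = np.zeros(m)
        e[j] = eps
        J[:, j] = (params.drift(S_star + e) - params.drift(S_star - e)) / (2 * eps)
    return J
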