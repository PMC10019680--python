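import numpy as np
import pytest

from metarecon import build_serine_network, make_ground_truth


@pytest.fixture(scope="session")
def serine_net():
    return build_serine_network()


@pytest.fixture(scope="session")
def serine_truth(serine_net):
    return make_ground_truth(serine_net, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_jacobian(n: int, rng: np.random.Generator) -> np.ndarray:
    """Dense Hurwitz-stable matrix: random + diagonal shift past the spectral abscissa."""
    a = rng.normal(size=(n, n))
    shift = np.abs(np.linalg.eigvals(a).real).max() + 0.5
    return a - shift * np.eye(n)


def lyapunov_vectorized_oracle(jac: np.ndarray, flu: np.ndarray) -> np.ndarray:
    """Independent forward solve via the n^2 x n^2 Kronecker linear system."""
    n = jac.shape[0]
    lhs = np.kron(np.eye(n), jac) + np.kron(jac, np.eye(n))
    c = np.linalg.solve(lhs, (-2.0 * flu).reshape(-1))
    return c.reshape(n, n)
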