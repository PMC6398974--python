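import numpy as np
import pytest

from olfadapt.model_core import NoiseProfile, OdorEnvironment, SensingMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_overlap(rng, m, spread=1.0):
    """Random well-conditioned PSD overlap matrix."""
    G = rng.standard_normal((m, 2 * m + 2)) * spread
    return G @ G.T


def random_instance(rng, m=4, n=10, sigma_lo=0.5, sigma_hi=2.0):
    """Random (S, env, noise) triple with a well-conditioned covariance."""
    S = SensingMatrix(rng.lognormal(0.0, 0.5, size=(m, n)))
    G = rng.standard_normal((n, 3 * n))
    env = OdorEnvironment(np.zeros(n), G @ G.T / (3 * n))
    noise = NoiseProfile(rng.uniform(sigma_lo, sigma_hi, m))
    return S, env, noise


def grid_search_max_info(Q, sigma2, Ktot, n_grid=2000):
    """Exhaustive simplex grid search of I for M in {2, 3}.

    Uses closed-form 2x2/3x3 determinants of I + diag(k) Sigma^-1 Q,
    vectorized over the grid, as an optimizer-independent oracle.
    """
    Q = np.asarray(Q, float)
    sigma2 = np.asarray(sigma2, float)
    G = Q / sigma2[:, None]  # Sigma^-1 Q
    m = Q.shape[0]
    ks = np.linspace(0.0, Ktot, n_grid + 1)
    if m == 2:
        k1 = ks
        k2 = Ktot - ks
        det = (1 + k1 * G[0, 0]) * (1 + k2 * G[1, 1]) - k1 * k2 * G[0, 1] * G[1, 0]
        return 0.5 * float(np.log(det).max())
    if m == 3:
        k1, k2 = np.meshgrid(ks, ks, indexing="ij")
        k3 = Ktot - k1 - k2
        ok = k3 >= 0
        k1, k2, k3 = k1[ok], k2[ok], k3[ok]
        a11 = 1 + k1 * G[0, 0]
        a12 = k1 * G[0, 1]
        a13 = k1 * G[0, 2]
        a21 = k2 * G[1, 0]
        a22 = 1 + k2 * G[1, 1]
        a23 = k2 * G[1, 2]
        a31 = k3 * G[2, 0]
        a32 = k3 * G[2, 1]
        a33 = 1 + k3 * G[2, 2]
        det = (
            a11 * (a22 * a33 - a23 * a32)
            - a12 * (a21 * a33 - a23 * a31)
            + a13 * (a21 * a32 - a22 * a31)
        )
        return 0.5 * float(np.log(det).max())
    raise ValueError("grid oracle supports M in {2, 3}")
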