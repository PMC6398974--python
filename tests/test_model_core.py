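import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olfadapt.model_core import (
    NoiseProfile,
    OdorEnvironment,
    ReceptorDistribution,
    SensingMatrix,
    mi_gradient,
    mutual_information,
    overlap_matrix,
    response_covariance,
)

from conftest import random_instance, random_overlap


class TestDomainTypes:
    def test_environment_validates_symmetry_and_psd(self):
        with pytest.raises(ValueError, match="symmetric"):
            OdorEnvironment(None, np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="positive semi-definite"):
            OdorEnvironment(None, np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_environment_clips_tiny_negative_eigenvalue(self):
        gamma = np.eye(2)
        gamma[1, 1] = -1e-12
        env = OdorEnvironment(None, gamma)
        assert np.linalg.eigvalsh(env.gamma).min() >= 0.0

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            SensingMatrix(np.ones((2, 2)), receptor_labels=("a", "a"))
        with pytest.raises(ValueError, match="unique"):
            OdorEnvironment(None, np.eye(2), odorant_labels=("x", "x"))

    def test_noise_must_be_positive(self):
        with pytest.raises(ValueError):
            NoiseProfile(np.array([1.0, 0.0]))

    def test_distribution_invariants(self):
        d = ReceptorDistribution(np.array([3.0, 7.0]), 10.0)
        assert d.fractions.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError, match="negative"):
            ReceptorDistribution(np.array([-1.0, 11.0]), 10.0)
        with pytest.raises(ValueError, match="differs from Ktot"):
            ReceptorDistribution(np.array([3.0, 3.0]), 10.0)


class TestOverlapMatrix:
    def test_identity_sensing_returns_gamma(self):
        gamma = np.array([[1.0, 0.5], [0.5, 1.0]])
        env = OdorEnvironment(None, gamma)
        assert np.allclose(overlap_matrix(np.eye(2), env), gamma)

    def test_summing_row_adds_variances(self):
        env = OdorEnvironment(None, np.eye(2))
        Q = overlap_matrix(np.array([[1.0, 1.0]]), env)
        assert Q == pytest.approx(np.array([[2.0]]))

    def test_dimension_mismatch(self):
        env = OdorEnvironment(None, np.eye(3))
        with pytest.raises(ValueError, match="odorant"):
            overlap_matrix(np.ones((2, 2)), env)

    def test_monte_carlo_oracle(self, rng):
        """Q equals the covariance of noiseless responses S c, c ~ N(c0, Gamma)."""
        S = rng.standard_normal((3, 5))
        G = rng.standard_normal((5, 12))
        gamma = G @ G.T / 12
        c0 = rng.standard_normal(5)
        env = OdorEnvironment(c0, gamma)
        Q = overlap_matrix(S, env)
        c = rng.multivariate_normal(c0, gamma, size=1_000_000)
        Q_mc = np.cov((c @ S.T).T)
        # sampling error of a covariance entry ~ scale/sqrt(n)
        tol = 5.0 * np.abs(Q).max() / np.sqrt(1_000_000)
        assert np.abs(Q - Q_mc).max() < 10 * tol

    def test_independent_of_mean(self, rng):
        S, env, _ = random_instance(rng)
        shifted = env.with_mean(rng.standard_normal(env.n_odorants))
        assert np.array_equal(overlap_matrix(S, env), overlap_matrix(S, shifted))


class TestResponseCovariance:
    def test_zero_population_gives_zero(self):
        env = OdorEnvironment(None, np.eye(2))
        R = response_covariance(np.zeros(2), np.eye(2), env, np.ones(2))
        assert np.all(R == 0)

    def test_scalar_arithmetic(self):
        env = OdorEnvironment(None, np.array([[3.0]]))
        R = response_covariance(np.array([2.0]), np.array([[1.0]]), env, np.array([1.0]))
        assert R == pytest.approx(np.array([[14.0]]))

    def test_negative_counts_rejected(self):
        env = OdorEnvironment(None, np.eye(2))
        with pytest.raises(ValueError, match="non-negative"):
            response_covariance(np.array([-1.0, 1.0]), np.eye(2), env, np.ones(2))

    def test_monte_carlo_simulator_oracle(self, rng):
        """R matches the covariance of simulated responses Ka*S@c + sqrt(Ka)*eta."""
        S, env, noise = random_instance(rng, m=3, n=6)
        K = rng.uniform(0.5, 4.0, 3)
        R = response_covariance(K, S, env, noise)
        n_samp = 400_000
        c = rng.multivariate_normal(env.c0, env.gamma, size=n_samp)
        eta = rng.standard_normal((n_samp, 3)) * np.sqrt(noise.sigma2)
        r = K * (c @ S.S.T) + np.sqrt(K) * eta
        R_mc = np.cov(r.T)
        assert np.abs(R - R_mc).max() < 10 * np.abs(R).max() / np.sqrt(n_samp) * 5


class TestMutualInformation:
    def test_zero_population_gives_zero_information(self):
        assert mutual_information(np.zeros(3), np.eye(3), np.ones(3)) == 0.0

    def test_scalar_channel_closed_form(self):
        # single channel: I = 1/2 log(1 + K Q / sigma^2)
        got = mutual_information(np.array([4.0]), np.array([[1.0]]), np.array([1.0]))
        assert got == pytest.approx(0.5 * np.log(5.0), rel=1e-12)

    def test_independent_channels_sum(self):
        Q = np.diag([2.0, 1.0])
        got = mutual_information(np.array([5.25, 4.75]), Q, np.ones(2))
        expected = 0.5 * (np.log(11.5) + np.log(5.75))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bits_conversion(self, rng):
        Q = random_overlap(rng, 3)
        K = rng.uniform(0, 2, 3)
        nats = mutual_information(K, Q, np.ones(3))
        bits = mutual_information(K, Q, np.ones(3), bits=True)
        assert bits == pytest.approx(nats / np.log(2.0))

    def test_nonnegative_and_zero_iff_silent(self, rng):
        Q = random_overlap(rng, 4)
        K = rng.uniform(0, 3, 4)
        assert mutual_information(K, Q, np.ones(4)) > 0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 10.0))
    def test_units_invariance(self, seed, scale):
        """Scaling S by s and Gamma by 1/s^2 leaves Q and I unchanged."""
        r = np.random.default_rng(seed)
        S, env, noise = random_instance(r, m=3, n=6)
        K = r.uniform(0, 5, 3)
        env_scaled = OdorEnvironment(env.c0, env.gamma / scale**2)
        Q1 = overlap_matrix(S.S, env)
        Q2 = overlap_matrix(scale * S.S, env_scaled)
        assert np.allclose(Q1, Q2, rtol=1e-9)
        i1 = mutual_information(K, Q1, noise)
        i2 = mutual_information(K, Q2, noise)
        assert i1 == pytest.approx(i2, rel=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), split=st.floats(0.0, 1.0))
    def test_glomerular_splitting_invariance(self, seed, split):
        """Duplicating a receptor row and splitting its K leaves I unchanged."""
        r = np.random.default_rng(seed)
        S, env, noise = random_instance(r, m=3, n=6)
        K = r.uniform(0.1, 5, 3)
        Q = overlap_matrix(S, env)
        i_orig = mutual_information(K, Q, noise)
        S2 = np.vstack([S.S, S.S[0]])
        Q2 = overlap_matrix(S2, env)
        sigma2_2 = np.append(noise.sigma2, noise.sigma2[0])
        K2 = np.append(K.copy(), 0.0)
        K2[3] = K[0] * split
        K2[0] = K[0] * (1 - split)
        i_split = mutual_information(K2, Q2, sigma2_2)
        assert i_split == pytest.approx(i_orig, rel=1e-9)


class TestGradient:
    def test_scalar_derivative_at_zero(self):
        g = mi_gradient(np.array([0.0]), np.array([[3.0]]), np.array([1.0]))
        assert g == pytest.approx(np.array([1.5]))

    def test_identical_receptors_get_equal_gradients(self, rng):
        S_row = rng.lognormal(0, 0.5, 6)
        S = np.vstack([S_row, S_row, rng.lognormal(0, 0.5, 6)])
        env = OdorEnvironment(None, np.eye(6))
        Q = overlap_matrix(S, env)
        K = np.array([2.0, 2.0, 1.0])
        g = mi_gradient(K, Q, np.ones(3))
        assert g[0] == pytest.approx(g[1], rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_finite_differences(self, seed):
        r = np.random.default_rng(seed)
        Q = random_overlap(r, 4)
        K = r.uniform(0.0, 5.0, 4)
        sigma2 = r.uniform(0.5, 2.0, 4)
        g = mi_gradient(K, Q, sigma2)
        eps = 1e-6
        for a in range(4):
            dk = np.zeros(4)
            dk[a] = eps
            fd = (
                mutual_information(K + dk, Q, sigma2)
                - mutual_information(np.clip(K - dk, 0, None), Q, sigma2)
            ) / (2 * eps)
            assert abs(g[a] - fd) < 1e-6 * max(1.0, abs(fd))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_gradient_nonnegative(self, seed):
        """I is non-decreasing in each Ka."""
        r = np.random.default_rng(seed)
        Q = random_overlap(r, 4)
        K = r.uniform(0.0, 10.0, 4)
        sigma2 = r.uniform(0.2, 3.0, 4)
        assert np.all(mi_gradient(K, Q, sigma2) >= 0)
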