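"""Core domain types and the Gaussian information objective.

The model treats an olfactory scene as a vector of odorant concentrations
``c ~ N(c0, Gamma)`` and the response of the glomerulus pooling the ``Ka``
sensory neurons of receptor type ``a`` as

    r_a = Ka * sum_i S_ai c_i + sqrt(Ka) * eta_a,    eta_a ~ N(0, sigma_a^2),

i.e. signal grows linearly with the number of neurons while the pooled noise
standard deviation grows as sqrt(Ka).  Under these Gaussian assumptions the
mutual information between responses and concentrations is

    I(r, c) = 1/2 Tr log(I + K Sigma^-1 Q),    Q = S Gamma S^T,

with K = diag(Ka) and Sigma = diag(sigma_a^2).  ``Q`` (the overlap matrix) is
the covariance of noiseless glomerular signals; ``K Sigma^-1 Q`` plays the
role of a squared signal-to-noise ratio generalized to correlated channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdorEnvironment",
    "SensingMatrix",
    "NoiseProfile",
    "ReceptorDistribution",
    "overlap_matrix",
    "response_covariance",
    "mutual_information",
    "mi_gradient",
]

#: eigenvalues of a covariance in [-PSD_RTOL * lambda_max, 0) are clipped to 0
PSD_RTOL = 1e-10


def _check_unique(labels: tuple[str, ...], what: str) -> None:
    if len(set(labels)) != len(labels):
        raise ValueError(f"{what} labels must be unique")


def _default_labels(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(n))


def _validate_psd(mat: np.ndarray, name: str) -> np.ndarray:
    """Check (near-)PSD-ness; clip tiny negative eigenvalues to zero.

    Eigenvalues below ``-PSD_RTOL * lambda_max`` raise; eigenvalues in the
    tolerance band are clipped and the matrix reconstructed.
    """
    w, v = np.linalg.eigh(mat)
    scale = max(w.max(), 0.0)
    if w.min() < -PSD_RTOL * scale - np.finfo(float).tiny:
        raise ValueError(
            f"{name} is not positive semi-definite: min eigenvalue "
            f"{w.min():.3e} (max {scale:.3e})"
        )
    if w.min() < 0.0:
        w = np.clip(w, 0.0, None)
        mat = (v * w) @ v.T
        mat = 0.5 * (mat + mat.T)
    return mat


@dataclass(frozen=True)
class OdorEnvironment:
    """Gaussian odor environment: mean concentrations ``c0`` and covariance ``gamma``.

    ``gamma`` must be symmetric and positive semi-definite (within tolerance;
    tiny negative eigenvalues are clipped).  The mean ``c0`` never influences
    the information objective, but is carried for completeness.
    """

    c0: np.ndarray
    gamma: np.ndarray
    odorant_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
            raise ValueError(f"gamma must be square, got shape {gamma.shape}")
        n = gamma.shape[0]
        c0 = np.zeros(n) if self.c0 is None else np.asarray(self.c0, dtype=float).ravel()
        if c0.shape != (n,):
            raise ValueError(f"c0 has length {c0.size}, expected {n}")
        if not np.all(np.isfinite(gamma)) or not np.all(np.isfinite(c0)):
            raise ValueError("environment entries must be finite")
        scale = np.abs(gamma).max() or 1.0
        if np.abs(gamma - gamma.T).max() > 1e-8 * scale:
            raise ValueError("gamma must be symmetric")
        gamma = _validate_psd(0.5 * (gamma + gamma.T), "gamma")
        labels = self.odorant_labels or _default_labels("odorant_", n)
        labels = tuple(str(x) for x in labels)
        if len(labels) != n:
            raise ValueError("odorant_labels length mismatch")
        _check_unique(labels, "odorant")
        object.__setattr__(self, "c0", c0)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "odorant_labels", labels)

    @property
    def n_odorants(self) -> int:
        return self.gamma.shape[0]

    def with_mean(self, c0: np.ndarray) -> "OdorEnvironment":
        return OdorEnvironment(np.asarray(c0, dtype=float), self.gamma, self.odorant_labels)


@dataclass(frozen=True)
class SensingMatrix:
    """M x N matrix of expected single-neuron responses per unit concentration."""

    S: np.ndarray
    receptor_labels: tuple[str, ...] = field(default=())
    odorant_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if not np.all(np.isfinite(S)):
            raise ValueError("sensing matrix entries must be finite")
        m, n = S.shape
        rlabels = self.receptor_labels or _default_labels("receptor_", m)
        olabels = self.odorant_labels or _default_labels("odorant_", n)
        rlabels = tuple(str(x) for x in rlabels)
        olabels = tuple(str(x) for x in olabels)
        if len(rlabels) != m or len(olabels) != n:
            raise ValueError("label length mismatch with sensing matrix shape")
        _check_unique(rlabels, "receptor")
        _check_unique(olabels, "odorant")
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "receptor_labels", rlabels)
        object.__setattr__(self, "odorant_labels", olabels)

    @property
    def n_receptors(self) -> int:
        return self.S.shape[0]

    @property
    def n_odorants(self) -> int:
        return self.S.shape[1]


@dataclass(frozen=True)
class NoiseProfile:
    """Per-receptor single-neuron noise variances sigma_a^2 (> 0)."""

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        if sigma2.size == 0 or not np.all(np.isfinite(sigma2)) or np.any(sigma2 <= 0):
            raise ValueError("noise variances must be finite and strictly positive")
        object.__setattr__(self, "sigma2", sigma2)

    @classmethod
    def uniform(cls, n_receptors: int, sigma2: float = 1.0) -> "NoiseProfile":
        return cls(np.full(n_receptors, float(sigma2)))

    @property
    def n_receptors(self) -> int:
        return self.sigma2.size


@dataclass(frozen=True)
class ReceptorDistribution:
    """Non-negative real OSN counts per receptor type, summing to ``Ktot``."""

    K: np.ndarray
    Ktot: float

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float).ravel()
        Ktot = float(self.Ktot)
        if Ktot <= 0 or not np.isfinite(Ktot):
            raise ValueError("Ktot must be positive and finite")
        if not np.all(np.isfinite(K)):
            raise ValueError("K must be finite")
        if K.min(initial=0.0) < -1e-9 * Ktot:
            raise ValueError(f"negative OSN count {K.min():.3e}")
        K = np.clip(K, 0.0, None)
        if abs(K.sum() - Ktot) > 1e-6 * Ktot:
            raise ValueError(f"sum(K) = {K.sum():.6g} differs from Ktot = {Ktot:.6g}")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "Ktot", Ktot)

    @property
    def n_receptors(self) -> int:
        return self.K.size

    @property
    def fractions(self) -> np.ndarray:
        return self.K / self.Ktot


def _as_k(K) -> np.ndarray:
    if isinstance(K, ReceptorDistribution):
        return K.K
    K = np.asarray(K, dtype=float).ravel()
    if not np.all(np.isfinite(K)):
        raise ValueError("K must be finite")
    if np.any(K < 0):
        raise ValueError("K must be non-negative")
    return K


def _as_sigma2(noise) -> np.ndarray:
    if isinstance(noise, NoiseProfile):
        return noise.sigma2
    return NoiseProfile(np.asarray(noise, dtype=float)).sigma2


def overlap_matrix(S: SensingMatrix | np.ndarray, env: OdorEnvironment) -> np.ndarray:
    """Covariance ``Q = S Gamma S^T`` of the noiseless glomerular signals.

    Independent of the mean concentration vector ``c0``.
    """
    Smat = S.S if isinstance(S, SensingMatrix) else np.atleast_2d(np.asarray(S, dtype=float))
    if Smat.shape[1] != env.n_odorants:
        raise ValueError(
            f"sensing matrix has {Smat.shape[1]} odorant columns but the "
            f"environment has {env.n_odorants} odorants"
        )
    Q = Smat @ env.gamma @ Smat.T
    return 0.5 * (Q + Q.T)


def response_covariance(K, S, env: OdorEnvironment, noise) -> np.ndarray:
    """Covariance ``R`` of glomerular responses, over odors and receptor noise.

    R = diag(K) Q diag(K) + diag(K) diag(sigma^2): signal covariance scaled by
    the neuron counts plus pooled (summed-neuron) noise on the diagonal.
    """
    k = _as_k(K)
    sigma2 = _as_sigma2(noise)
    Q = overlap_matrix(S, env)
    if not (k.size == sigma2.size == Q.shape[0]):
        raise ValueError("inconsistent receptor dimensions")
    R = (k[:, None] * Q) * k[None, :] + np.diag(k * sigma2)
    return 0.5 * (R + R.T)


def mutual_information(K, Q: np.ndarray, noise, *, bits: bool = False) -> float:
    """Mutual information ``1/2 Tr log(I + K Sigma^-1 Q)`` in nats (or bits).

    Evaluated through the symmetric similarity D Q D with
    D = diag(sqrt(Ka / sigma_a^2)), which has the same spectrum and is
    numerically stable.  Non-negative; zero iff the scaled signal vanishes.
    """
    k = _as_k(K)
    sigma2 = _as_sigma2(noise)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if not np.all(np.isfinite(Q)):
        raise ValueError("Q must be finite")
    d = np.sqrt(k / sigma2)
    B = (d[:, None] * Q) * d[None, :]
    w = np.linalg.eigvalsh(0.5 * (B + B.T))
    info = 0.5 * float(np.sum(np.log1p(np.clip(w, 0.0, None))))
    return info / np.log(2.0) if bits else info


def mi_gradient(K, Q: np.ndarray, noise) -> np.ndarray:
    """Gradient of :func:`mutual_information` with respect to ``Ka`` (nats/neuron).

    Component a is ``1/2 [(Sigma + Q K)^-1 Q]_aa``, an algebraic rewriting of
    ``1/2 [Sigma^-1 Q (I + K Sigma^-1 Q)^-1]_aa`` that stays well-posed for all
    feasible inputs (``Sigma + Q K`` is always invertible).  Components are
    non-negative.
    """
    k = _as_k(K)
    sigma2 = _as_sigma2(noise)
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if not np.all(np.isfinite(Q)):
        raise ValueError("Q must be finite")
    A = Q * k[None, :] + np.diag(sigma2)  # Sigma + Q K
    W = np.linalg.solve(A, Q)
    return np.clip(0.5 * np.diagonal(W), 0.0, None).copy()


def _mi_hessian_factor(k: np.ndarray, Q: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """Return W = (Sigma + Q K)^-1 Q; the Hessian of I is -1/2 (W * W^T)."""
    A = Q * k[None, :] + np.diag(sigma2)
    return np.linalg.solve(A, Q)
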