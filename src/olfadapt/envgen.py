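"""Random odor-environment and sensing-matrix ensembles.

Environments are random covariance matrices Gamma = D^{1/2} C D^{1/2}: a
random correlation matrix C built by normalizing G G^T (G an N x ceil(beta*N)
standard-normal matrix; larger ``beta`` gives weaker off-diagonal
correlations) scaled by lognormally distributed per-odorant variances D.
Perturbation recipes on top of a base environment model the in-silico
experiments: raising single or grouped odorant variances, engineering pairs
of environments with non-overlapping odor content, and small jitter applied
to the matrix square root (which preserves positive semi-definiteness by
construction).

Sensing matrices are generated with a controlled tuning width: each receptor
responds strongly to a fixed fraction of the odorants and only weakly to the
rest.  Wider tuning produces more correlated glomerular responses.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_core import OdorEnvironment, SensingMatrix

__all__ = [
    "EnvironmentEnsembleParams",
    "PerturbationSpec",
    "random_environment",
    "perturb_single_variance",
    "perturb_variance_set",
    "nonoverlapping_pair",
    "jitter_sqrt",
    "random_sensing_matrix",
]


@dataclass(frozen=True)
class EnvironmentEnsembleParams:
    """Knobs of the random-covariance ensemble.

    ``beta`` controls correlation strength (columns of the Gram factor per
    odorant; 8 reproduces the weakly correlated regime used for the
    environment-change experiments).  Per-odorant variances are
    lognormal(``logvar_mu``, ``logvar_sigma``).
    """

    n_odorants: int
    beta: float = 8.0
    logvar_mu: float = 0.0
    logvar_sigma: float = 1.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_odorants < 1:
            raise ValueError("n_odorants must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.logvar_sigma < 0:
            raise ValueError("logvar_sigma must be non-negative")


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative description of an environment perturbation."""

    kind: str  # single_variance | variance_set | nonoverlapping_pair | sqrt_jitter
    indices: tuple[int, ...] = field(default=())
    magnitude: float = 0.0
    seed: int | None = None

    _KINDS = ("single_variance", "variance_set", "nonoverlapping_pair", "sqrt_jitter")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))


def _correlation_matrix(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    G = rng.standard_normal((n, math.ceil(beta * n)))
    C = G @ G.T
    d = np.sqrt(np.diagonal(C))
    C = C / np.outer(d, d)
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


def random_environment(params: EnvironmentEnsembleParams) -> OdorEnvironment:
    """Draw one random odor environment (zero mean)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_odorants
    C = _correlation_matrix(n, params.beta, rng)
    variances = rng.lognormal(params.logvar_mu, params.logvar_sigma, size=n)
    d = np.sqrt(variances)
    gamma = C * np.outer(d, d)
    return OdorEnvironment(np.zeros(n), gamma)


def perturb_single_variance(
    env: OdorEnvironment, odorant_index: int, added_variance: float
) -> OdorEnvironment:
    """Increase the variance of one odorant: Gamma' = Gamma + v * e_i e_i^T."""
    if added_variance < 0:
        raise ValueError("added_variance must be non-negative")
    n = env.n_odorants
    if not 0 <= odorant_index < n:
        raise IndexError(f"odorant index {odorant_index} out of range [0, {n})")
    gamma = env.gamma.copy()
    gamma[odorant_index, odorant_index] += added_variance
    return OdorEnvironment(env.c0, gamma, env.odorant_labels)


def perturb_variance_set(env: OdorEnvironment, indices, added_variance: float) -> OdorEnvironment:
    """Increase the variance of a set of odorants (10 in the reference setup)."""
    if added_variance < 0:
        raise ValueError("added_variance must be non-negative")
    idx = [int(i) for i in indices]
    n = env.n_odorants
    for i in idx:
        if not 0 <= i < n:
            raise IndexError(f"odorant index {i} out of range [0, {n})")
    gamma = env.gamma.copy()
    gamma[idx, idx] += added_variance
    return OdorEnvironment(env.c0, gamma, env.odorant_labels)


def nonoverlapping_pair(
    params: EnvironmentEnsembleParams,
    split_seed: int | None = None,
    *,
    floor_factor: float = 1e-4,
) -> tuple[OdorEnvironment, OdorEnvironment]:
    """A pair of environments with largely non-overlapping odor content.

    Odorants are randomly split in two halves; each environment keeps the
    generic-ensemble variance structure on its half and is damped to a floor
    variance (``floor_factor`` x median generic variance) on the other, so
    every odorant has appreciable variance in at most one of the two.
    """
    n = params.n_odorants
    if n < 2:
        raise ValueError("need at least 2 odorants to build a non-overlapping pair")
    base = random_environment(params)
    rng = np.random.default_rng(params.seed if split_seed is None else split_seed)
    perm = rng.permutation(n)
    half1 = np.zeros(n, dtype=bool)
    half1[perm[: n // 2]] = True
    floor = floor_factor * float(np.median(np.diagonal(base.gamma)))

    def _restrict(keep: np.ndarray) -> OdorEnvironment:
        var = np.diagonal(base.gamma)
        scale = np.where(keep, 1.0, np.sqrt(floor / var))
        gamma = base.gamma * np.outer(scale, scale)
        return OdorEnvironment(base.c0, gamma, base.odorant_labels)

    return _restrict(half1), _restrict(~half1)


def jitter_sqrt(
    env: OdorEnvironment, jitter_scale: float, seed: int | None = None
) -> OdorEnvironment:
    """Perturb a covariance by Gaussian noise on its symmetric square root.

    Gamma' = (Gamma^{1/2} + eps Z)(Gamma^{1/2} + eps Z)^T, a Gram matrix and
    hence PSD for any jitter.  ||Gamma' - Gamma|| grows linearly in eps to
    first order.
    """
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be non-negative")
    w, v = np.linalg.eigh(env.gamma)
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal(root.shape)
    jittered = root + jitter_scale * Z
    gamma = jittered @ jittered.T
    return OdorEnvironment(env.c0, 0.5 * (gamma + gamma.T), env.odorant_labels)


def random_sensing_matrix(
    n_receptors: int,
    n_odorants: int,
    tuning_width: float,
    *,
    seed: int | None = 0,
    strong_mu: float = 0.0,
    strong_sigma: float = 0.5,
    weak_scale: float = 0.02,
) -> SensingMatrix:
    """Random non-negative sensing matrix with controlled tuning width.

    Each receptor row has ``round(tuning_width * N)`` strong entries at random
    positions, with magnitudes lognormal(``strong_mu``, ``strong_sigma``);
    the remaining entries are weak (same distribution scaled by
    ``weak_scale``).
    """
    if n_receptors < 1 or n_odorants < 1:
        raise ValueError("matrix dimensions must be >= 1")
    if not 0 < tuning_width <= 1:
        raise ValueError("tuning_width must be in (0, 1]")
    n_strong = int(round(tuning_width * n_odorants))
    if n_strong < 1:
        raise ValueError(
            f"tuning_width {tuning_width} selects no odorants for N={n_odorants}; "
            "use a larger N or wider tuning"
        )
    rng = np.random.default_rng(seed)
    S = weak_scale * rng.lognormal(strong_mu, strong_sigma, size=(n_receptors, n_odorants))
    for a in range(n_receptors):
        cols = rng.choice(n_odorants, size=n_strong, replace=False)
        S[a, cols] = rng.lognormal(strong_mu, strong_sigma, size=n_strong)
    return SensingMatrix(S)
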