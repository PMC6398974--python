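"""Information-maximizing allocation of OSNs across receptor types.

Solves

    maximize  I(K) = 1/2 Tr log(I + K Sigma^-1 Q)
    subject to  sum_a Ka = Ktot,  Ka >= 0,

a concave maximization over the simplex (logdet of an affine PSD map), so the
optimal value is unique.  The solver combines SLSQP on the normalized scale
x = K/Ktot with an active-set Newton polish that drives the KKT residual to
machine precision: at the optimum the information gradient is equal (= mu)
over all expressed receptor types and no larger than mu for unexpressed ones.

Analytic limits from the theory are provided as independent references:
``highsnr_distribution`` (abundances deviate from uniform by sigma_a^2 times
the diagonal of the inverse overlap matrix) and ``lowsnr_support`` (all
neurons on the receptor with the largest Qaa/sigma_a^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model_core import (
    NoiseProfile,
    OdorEnvironment,
    ReceptorDistribution,
    SensingMatrix,
    _as_k,
    _as_sigma2,
    _mi_hessian_factor,
    mi_gradient,
    mutual_information,
    overlap_matrix,
)

__all__ = [
    "OptimizationResult",
    "optimal_distribution",
    "optimal_distribution_from_overlap",
    "highsnr_distribution",
    "lowsnr_support",
    "kkt_residual",
    "receptor_count_curve",
]


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the constrained information maximization."""

    distribution: ReceptorDistribution
    info: float
    gradient: np.ndarray
    kkt_residual: float
    multiplier: float
    n_restarts_used: int
    converged: bool

    @property
    def K(self) -> np.ndarray:
        return self.distribution.K


def kkt_residual(K, Q: np.ndarray, noise, Ktot: float, *, active_tol: float | None = None):
    """Normalized KKT residual of a feasible allocation; 0 at a true optimum.

    Receptors with ``Ka > active_tol`` (default ``1e-6 * Ktot / M``) form the
    active set.  mu-hat is the largest gradient over the active set; the
    residual is the larger of the gradient spread over the active set and the
    worst positive excess ``gradient_a - mu_hat`` over inactive receptors,
    normalized by mu-hat.  Returns ``(residual, mu_hat)``.
    """
    k = _as_k(K)
    Ktot = float(Ktot)
    m = k.size
    if active_tol is None:
        active_tol = 1e-6 * Ktot / m
    active = k > active_tol
    if not np.any(active):
        raise ValueError("empty active set: no receptor exceeds active_tol")
    g = mi_gradient(k, Q, noise)
    mu_hat = float(g[active].max())
    spread = float(g[active].max() - g[active].min())
    excess = float(np.clip(g[~active] - mu_hat, 0.0, None).max()) if np.any(~active) else 0.0
    denom = mu_hat if mu_hat > 0 else 1.0
    return max(spread, excess) / denom, mu_hat


def _polish_active_set(
    k: np.ndarray,
    Q: np.ndarray,
    sigma2: np.ndarray,
    Ktot: float,
    *,
    active_tol: float,
    max_outer: int = 40,
    max_newton: int = 60,
) -> np.ndarray:
    """Equality-constrained Newton refinement on the current active set.

    The Hessian of I is -1/2 (W o W^T) with W = (Sigma + QK)^-1 Q, so Newton
    steps on the KKT system {grad_a = mu on the active set, sum K = Ktot} are
    cheap and quadratically convergent.  Receptors pushed below zero are
    dropped; inactive receptors whose gradient exceeds mu are re-added.
    """
    m = k.size
    k = np.clip(k.copy(), 0.0, None)
    active = k > active_tol
    if not np.any(active):
        active[int(np.argmax(k))] = True
    for _ in range(max_outer):
        idx = np.flatnonzero(active)
        ka = k[idx]
        # project onto the face and renormalize
        ka = np.clip(ka, 0.0, None)
        ka *= Ktot / ka.sum()
        converged_inner = False
        for _ in range(max_newton):
            full = np.zeros(m)
            full[idx] = ka
            W = _mi_hessian_factor(full, Q, sigma2)
            g = np.clip(0.5 * np.diagonal(W), 0.0, None)
            H = -0.5 * (W * W.T)
            Ha = H[np.ix_(idx, idx)]
            na = idx.size
            kkt = np.zeros((na + 1, na + 1))
            kkt[:na, :na] = Ha
            kkt[:na, na] = -1.0
            kkt[na, :na] = 1.0
            rhs = np.concatenate([-g[idx], [0.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                return np.clip(full, 0.0, None)
            dk = sol[:na]
            # damped step keeping ka >= 0 (entries already at 0 are clipped after)
            step = 1.0
            neg = (dk < 0) & (ka > 0)
            if np.any(neg):
                step = min(1.0, 0.9999 * np.min(-ka[neg] / dk[neg]))
                step = max(step, 0.0)
            ka = ka + step * dk
            ka = np.clip(ka, 0.0, None)
            s = ka.sum()
            if s > 0:
                ka *= Ktot / s
            if step * np.abs(dk).max() <= 1e-13 * max(Ktot, 1.0):
                converged_inner = True
                break
        full = np.zeros(m)
        full[idx] = ka
        g = mi_gradient(full, Q, sigma2)
        mu = float(np.median(g[idx][ka > active_tol])) if np.any(ka > active_tol) else 0.0
        drop = idx[ka <= active_tol]
        add = np.flatnonzero(~active & (g > mu * (1.0 + 1e-10)))
        if drop.size == 0 and add.size == 0 and converged_inner:
            return full
        active[drop] = False
        active[add] = True
        if not np.any(active):
            active[int(np.argmax(g))] = True
        k = full
    return np.clip(k, 0.0, None)


def optimal_distribution_from_overlap(
    Q: np.ndarray,
    noise,
    Ktot: float,
    *,
    restarts: int = 5,
    tol: float = 1e-6,
    maxiter: int = 10_000,
    seed: int | None = 0,
) -> OptimizationResult:
    """Maximize I over the simplex given an overlap matrix ``Q`` directly."""
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    sigma2 = _as_sigma2(noise)
    Ktot = float(Ktot)
    if Ktot <= 0:
        raise ValueError("Ktot must be positive")
    m = Q.shape[0]
    if sigma2.size != m:
        raise ValueError("noise profile dimension does not match Q")
    if m == 1:
        K = np.array([Ktot])
        info = mutual_information(K, Q, sigma2)
        g = mi_gradient(K, Q, sigma2)
        return OptimizationResult(
            ReceptorDistribution(K, Ktot), info, g, 0.0, float(g[0]), 0, True
        )

    rng = np.random.default_rng(seed)
    active_tol = 1e-9 * Ktot / m

    def neg_f(x):
        return -mutual_information(Ktot * np.clip(x, 0.0, None), Q, sigma2)

    def neg_g(x):
        return -Ktot * mi_gradient(Ktot * np.clip(x, 0.0, None), Q, sigma2)

    constraints = [{"type": "eq", "fun": lambda x: x.sum() - 1.0, "jac": lambda x: np.ones(m)}]
    bounds = [(0.0, 1.0)] * m

    starts = [np.full(m, 1.0 / m)]
    starts += [rng.dirichlet(np.ones(m)) for _ in range(max(restarts, 0))]

    best_k = None
    best_info = -np.inf
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = minimize(
            neg_f,
            x0,
            jac=neg_g,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": min(maxiter, 1000), "ftol": 1e-14},
        )
        k_try = Ktot * np.clip(res.x, 0.0, None)
        s = k_try.sum()
        if s > 0:
            k_try *= Ktot / s
        k_try = _polish_active_set(k_try, Q, sigma2, Ktot, active_tol=active_tol)
        info_try = mutual_information(k_try, Q, sigma2)
        if info_try > best_info:
            best_info = info_try
            best_k = k_try
        # concave problem: a KKT-satisfying point is globally optimal
        resid, _ = kkt_residual(best_k, Q, sigma2, Ktot, active_tol=active_tol)
        if resid <= tol:
            break

    resid, mu = kkt_residual(best_k, Q, sigma2, Ktot, active_tol=active_tol)
    converged = resid <= tol
    if not converged:
        warnings.warn(
            f"optimizer did not reach KKT residual {tol:g} "
            f"(achieved {resid:.3e} after {n_used} starts)",
            RuntimeWarning,
            stacklevel=2,
        )
    g = mi_gradient(best_k, Q, sigma2)
    return OptimizationResult(
        ReceptorDistribution(best_k, Ktot), best_info, g, resid, mu, n_used, converged
    )


def optimal_distribution(
    S: SensingMatrix,
    env: OdorEnvironment,
    noise,
    Ktot: float,
    **options,
) -> OptimizationResult:
    """Information-optimal OSN allocation for a sensing matrix and environment."""
    Q = overlap_matrix(S, env)
    return optimal_distribution_from_overlap(Q, noise, Ktot, **options)


def highsnr_distribution(Q: np.ndarray, noise, Ktot: float, *, project: bool = False):
    """Closed-form large-population limit of the optimal allocation.

    ``Ka = Ktot/M - (sigma_a^2 A_aa - mean_b sigma_b^2 A_bb)`` with
    ``A = Q^-1``: near-uniform, with deviations set by the noise-scaled
    diagonal of the inverse overlap matrix.  Sums to ``Ktot`` exactly; may
    contain negative entries (returned raw unless ``project=True``, which
    projects onto the simplex).
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    sigma2 = _as_sigma2(noise)
    m = Q.shape[0]
    try:
        A = np.linalg.solve(Q, np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "overlap matrix is singular; the high-SNR formula needs Q^-1 "
            "(consider regularizing Q or removing redundant receptors)"
        ) from exc
    dev = sigma2 * np.diagonal(A)
    K = Ktot / m - (dev - dev.mean())
    if project:
        K = _project_simplex(K, float(Ktot))
    return K

def _project_simplex(v: np.ndarray, total: float) -> np.ndarray:
    """Euclidean projection onto {x >= 0, sum x = total}."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - total
    rho = np.nonzero(u - css / (np.arange(v.size) + 1) > 0)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


def lowsnr_support(Q: np.ndarray, noise) -> int:
    """Receptor that receives all neurons in the small-population limit.

    Returns ``argmax_a Qaa / sigma_a^2``; ties broken by lowest index.
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    sigma2 = _as_sigma2(noise)
    return int(np.argmax(np.diagonal(Q) / sigma2))


def receptor_count_curve(
    S: SensingMatrix,
    env: OdorEnvironment,
    noise,
    Ktot_grid,
    expression_threshold: float = 1e-3,
    **options,
):
    """Number of expressed receptor types as the OSN budget grows.

    A receptor counts as expressed when ``Ka > expression_threshold * Ktot/M``.
    Diversity grows in step transitions from 1 (tiny populations focus all
    neurons on the single best receptor) to M (large populations use every
    type nearly uniformly).
    """
    grid = np.asarray(Ktot_grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("Ktot_grid must be non-empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("Ktot_grid must be strictly increasing")
    Q = overlap_matrix(S, env)
    m = Q.shape[0]
    counts = np.empty(grid.size, dtype=int)
    for i, ktot in enumerate(grid):
        res = optimal_distribution_from_overlap(Q, noise, ktot, **options)
        counts[i] = int(np.sum(res.K > expression_threshold * ktot / m))
    return counts
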