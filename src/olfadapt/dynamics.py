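"""Experience-dependent birth/death dynamics of OSN abundances.

Receptor-type populations evolve under

    dKa/dt = alpha * ( Ka - lam * Ka^2 - sigma_a^2 (R^-1)_aa Ka^2 ),

where ``alpha`` is a learning rate, ``lam`` a density-dependent death
coefficient and ``R`` the covariance of glomerular responses at the current
abundances.  Birth is experience-independent; the death rate carries the
olfactory-experience signal through the inverse response covariance.  Without
the experience term the dynamics are plain logistic growth with fixed point
``Ka = 1/lam`` (total ``M/lam``).  With it, interior fixed points satisfy the
KKT conditions of the constrained information maximization at the emergent
total ``sum Ka``, so the epithelium converges to the efficient-coding optimum.

The experience term is evaluated through the factorization
``R = diag(K) (Q diag(K) + Sigma)``, giving
``sigma_a^2 (R^-1)_aa Ka^2 = sigma_a^2 Ka [(Q diag(K) + Sigma)^-1]_aa``,
which stays finite as Ka -> 0 where R itself becomes singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .model_core import (
    NoiseProfile,
    OdorEnvironment,
    ReceptorDistribution,
    SensingMatrix,
    _as_k,
    _as_sigma2,
    overlap_matrix,
)
from .optimize import kkt_residual

__all__ = [
    "DynamicsParams",
    "DynamicsTrajectory",
    "ConvergenceReport",
    "simulate_dynamics",
    "convergence_report",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the birth/death integration.

    ``dt`` defaults to ``0.01 / alpha`` so that ``alpha * dt <= 1e-2``;
    ``noise_floor`` is the abundance below which a population is treated as
    extinct for overshoot checks.  ``cache_steps`` controls how often the
    experience term is recomputed (1 = every Euler step).
    """

    alpha: float = 1.0
    lam: float = 1e-2
    dt: float | None = None
    t_max: float = 1e3
    noise_floor: float = 1e-8
    cache_steps: int = 1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lam must be positive")
        dt = 0.01 / self.alpha if self.dt is None else float(self.dt)
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= dt:
            raise ValueError("t_max must exceed dt")
        if self.cache_steps < 1:
            raise ValueError("cache_steps must be >= 1")
        object.__setattr__(self, "dt", dt)


@dataclass(frozen=True)
class DynamicsTrajectory:
    """Logged abundance path (log-spaced times) and endpoint diagnostics."""

    times: np.ndarray
    K_path: np.ndarray
    K_final: np.ndarray
    kkt_residual_final: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        P = np.atleast_2d(np.asarray(self.K_path, dtype=float))
        if t.size != P.shape[0]:
            raise ValueError("times and K_path disagree in length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if P.min(initial=0.0) < 0:
            raise ValueError("K_path must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "K_path", P)
        object.__setattr__(self, "K_final", np.asarray(self.K_final, dtype=float))


def _experience_term(k: np.ndarray, Q: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """sigma_a^2 (R^-1)_aa Ka^2, finite for Ka -> 0."""
    B = Q * k[None, :] + np.diag(sigma2)
    try:
        diag_inv = np.diagonal(np.linalg.solve(B, np.eye(k.size)))
    except np.linalg.LinAlgError:
        # Sigma > 0 makes B invertible for valid inputs; keep a guarded fallback
        diag_inv = np.diagonal(np.linalg.pinv(B))
    return sigma2 * k * diag_inv


def simulate_dynamics(
    K0,
    S: SensingMatrix,
    env: OdorEnvironment,
    noise,
    params: DynamicsParams,
    *,
    experience_term: bool = True,
    n_log: int = 200,
) -> DynamicsTrajectory:
    """Integrate the birth/death ODE by explicit Euler with overshoot control.

    Abundances are clipped at zero; if a single step would overshoot below
    ``-noise_floor`` the step is retried with a halved dt.  The trajectory is
    logged on a log-spaced time grid (plus t = 0 and t_max).
    """
    k = np.clip(_as_k(K0), 0.0, None)
    sigma2 = _as_sigma2(noise)
    Q = overlap_matrix(S, env)
    m = k.size
    if sigma2.size != m or Q.shape[0] != m:
        raise ValueError("inconsistent receptor dimensions")

    dt0 = float(params.dt)
    log_times = np.unique(
        np.concatenate([[0.0], np.geomspace(dt0, params.t_max, max(n_log - 1, 2))])
    )
    times_out: list[float] = [0.0]
    path: list[np.ndarray] = [k.copy()]
    next_log = 1

    t = 0.0
    exp_term = _experience_term(k, Q, sigma2) if experience_term else np.zeros(m)
    step_count = 0
    while t < params.t_max - 1e-12 * params.t_max:
        if experience_term and step_count % params.cache_steps == 0:
            exp_term = _experience_term(k, Q, sigma2)
        deriv = params.alpha * (k - params.lam * k**2 - exp_term)
        dt = min(dt0, params.t_max - t)
        k_new = k + dt * deriv
        n_halve = 0
        while k_new.min() < -params.noise_floor and n_halve < 60:
            dt *= 0.5
            k_new = k + dt * deriv
            n_halve += 1
        k = np.clip(k_new, 0.0, None)
        t += dt
        step_count += 1
        crossed = False
        while next_log < log_times.size and t >= log_times[next_log] - 1e-12:
            next_log += 1
            crossed = True
        if crossed:
            times_out.append(t)
            path.append(k.copy())

    if times_out[-1] < t:
        times_out.append(t)
        path.append(k.copy())

    ktot = float(k.sum())
    if ktot > 0:
        resid, _ = kkt_residual(k, Q, sigma2, ktot)
    else:
        resid = float("nan")
    return DynamicsTrajectory(np.array(times_out), np.vstack(path), k, resid)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-receptor convergence times against a target allocation."""

    convergence_times: np.ndarray  # nan where unreached
    reached: np.ndarray
    final_errors: np.ndarray
    rank_correlation: float  # spearman corr between target Ka and convergence time
    tolerance: float


def convergence_report(
    traj: DynamicsTrajectory,
    K_opt: ReceptorDistribution | np.ndarray,
    *,
    tol_fraction: float = 0.05,
) -> ConvergenceReport:
    """First times at which each ``|Ka(t) - Ka_opt|`` stays within tolerance.

    The tolerance is ``tol_fraction * Ktot / M`` (5% of the mean abundance by
    default).  Receptors never settling inside the band are flagged.  The
    summary rank correlation (target abundance vs convergence time) is
    typically negative: scarce receptor types converge more slowly, since
    dKa/dt vanishes as Ka -> 0.
    """
    k_opt = _as_k(K_opt)
    P = traj.K_path
    if P.shape[1] != k_opt.size:
        raise ValueError("trajectory and target disagree in receptor count")
    m = k_opt.size
    ktot = float(k_opt.sum())
    tol = tol_fraction * ktot / m
    err = np.abs(P - k_opt[None, :])
    inside = err <= tol
    conv_t = np.full(m, np.nan)
    reached = np.zeros(m, dtype=bool)
    for a in range(m):
        # last index where the receptor is outside the band
        outside = np.flatnonzero(~inside[:, a])
        if outside.size == 0:
            conv_t[a] = 0.0
            reached[a] = True
        elif outside[-1] + 1 < P.shape[0]:
            conv_t[a] = traj.times[outside[-1] + 1]
            reached[a] = True
    finite = reached & np.isfinite(conv_t)
    if finite.sum() >= 3 and np.unique(k_opt[finite]).size > 1 and np.unique(conv_t[finite]).size > 1:
        rho = float(spearmanr(k_opt[finite], conv_t[finite]).statistic)
    else:
        rho = float("nan")
    return ConvergenceReport(conv_t, reached, err[-1], rho, tol)
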