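"""In-silico experiment drivers built on the optimizer.

These reproduce the model's characteristic phenomena at configurable scale:

* ``delta_k_experiment`` — distributions of per-receptor abundance changes
  (Delta K) between pairs of environments, with summary fractions at fixed
  thresholds; non-overlapping environment pairs push changes toward both
  extremes (near zero and large) compared to generic pairs.
* ``context_dependence_experiment`` — the same single-odorant variance
  increase applied in two different background environments can move a
  receptor's optimal abundance in opposite directions.
* ``tuning_correlation_sweep`` — narrow tuning makes per-receptor SNR
  (Qaa/sigma_a^2) predictive of abundance; for wide tuning only the
  noise-scaled diagonal of the inverse overlap matrix remains predictive.
* ``subsampling_experiment`` — robustness of predicted abundances to removing
  receptors or odorants from the inputs.
* ``exposure_insilico`` — log-ratio of optimal abundances between two
  environments versus baseline abundance, with replicate ranges under small
  square-root jitter of both covariances.

Every driver is reproducible from (parameters, seed) and records the seed in
its result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .envgen import (
    EnvironmentEnsembleParams,
    jitter_sqrt,
    perturb_single_variance,
    random_environment,
    random_sensing_matrix,
)
from .model_core import (
    NoiseProfile,
    OdorEnvironment,
    SensingMatrix,
    _as_sigma2,
    overlap_matrix,
)
from .optimize import optimal_distribution_from_overlap

__all__ = [
    "DeltaKResult",
    "ContextDependenceResult",
    "TuningSweepResult",
    "SubsamplingResult",
    "ExposureResult",
    "delta_k_experiment",
    "context_dependence_experiment",
    "tuning_correlation_sweep",
    "subsampling_experiment",
    "exposure_insilico",
]

#: default |Delta K| cuts: near-zero, mid-range, extreme, and 20% of the mean
DELTAK_THRESHOLDS = (0.1, 50.0, 800.0)


def _optimize(Q, noise, Ktot, opt_options):
    opts = {"restarts": 1, "seed": 0}
    opts.update(opt_options or {})
    return optimal_distribution_from_overlap(Q, noise, Ktot, **opts)


@dataclass(frozen=True)
class DeltaKResult:
    deltas: np.ndarray  # pooled Delta K over pairs (n_pairs * M entries)
    per_pair: list
    fractions: dict
    n_pairs: int
    n_excluded: int
    seed: int | None


def delta_k_experiment(
    S: SensingMatrix,
    noise,
    Ktot: float,
    env_pairs,
    *,
    thresholds=DELTAK_THRESHOLDS,
    mean_fraction: float = 0.2,
    seed: int | None = None,
    opt_options: dict | None = None,
) -> DeltaKResult:
    """Optimal-abundance changes across a list of environment pairs.

    For each pair (env, env') the optimizer is run twice and
    Delta K_a = K'_a - K_a recorded.  Summary fractions report
    P(|dK| < t_low), P(|dK| > t_mid), P(|dK| > t_high) for the configured
    thresholds, plus P(|dK| < mean_fraction * Ktot / M).  Pairs on which the
    optimizer fails to converge are excluded with a warning.
    """
    sigma2 = _as_sigma2(noise)
    m = S.n_receptors
    deltas = []
    per_pair = []
    n_excluded = 0
    for i, (env_a, env_b) in enumerate(env_pairs):
        res_a = _optimize(overlap_matrix(S, env_a), sigma2, Ktot, opt_options)
        res_b = _optimize(overlap_matrix(S, env_b), sigma2, Ktot, opt_options)
        if not (res_a.converged and res_b.converged):
            warnings.warn(f"pair {i}: optimizer did not converge; excluded", RuntimeWarning)
            n_excluded += 1
            continue
        per_pair.append((res_a.K, res_b.K))
        deltas.append(res_b.K - res_a.K)
    deltas = np.concatenate(deltas) if deltas else np.empty(0)
    a = np.abs(deltas)
    t_low, t_mid, t_high = thresholds
    n = max(a.size, 1)
    fractions = {
        f"frac_below_{t_low:g}": float(np.sum(a < t_low)) / n,
        f"frac_above_{t_mid:g}": float(np.sum(a > t_mid)) / n,
        f"frac_above_{t_high:g}": float(np.sum(a > t_high)) / n,
        "frac_below_mean_fraction": float(np.sum(a < mean_fraction * Ktot / m)) / n,
    }
    return DeltaKResult(deltas, per_pair, fractions, len(per_pair), n_excluded, seed)


@dataclass(frozen=True)
class ContextDependenceResult:
    delta1: np.ndarray  # (n_pairs, M) change in background 1
    delta2: np.ndarray  # (n_pairs, M) change in background 2
    opposite_sign_fraction: float
    n_both_nonzero: int
    seed: int | None


def context_dependence_experiment(
    S: SensingMatrix,
    noise,
    Ktot: float,
    n_pairs: int,
    *,
    env_params: EnvironmentEnsembleParams | None = None,
    added_variance: float | None = None,
    seed: int | None = 0,
    zero_tol: float | None = None,
    opt_options: dict | None = None,
) -> ContextDependenceResult:
    """Apply the same odorant-variance increase in two different backgrounds.

    For each of ``n_pairs`` draws, two independent background environments are
    generated, the variance of one randomly chosen odorant is increased by the
    same amount in both, and the induced abundance changes (dK1, dK2) are
    recorded per receptor.  Reports the fraction of receptors (both changes
    nonzero) whose changes have opposite signs — the signature of
    context-dependent adaptation.
    """
    sigma2 = _as_sigma2(noise)
    n = S.n_odorants
    if env_params is None:
        env_params = EnvironmentEnsembleParams(n_odorants=n)
    if env_params.n_odorants != n:
        raise ValueError("env_params odorant count must match the sensing matrix")
    rng = np.random.default_rng(seed)
    if zero_tol is None:
        zero_tol = 1e-6 * Ktot / S.n_receptors
    d1, d2 = [], []
    for _ in range(n_pairs):
        s1, s2_, = rng.integers(0, 2**31, size=2)
        envs = [
            random_environment(
                EnvironmentEnsembleParams(
                    n, env_params.beta, env_params.logvar_mu, env_params.logvar_sigma, int(s)
                )
            )
            for s in (s1, s2_)
        ]
        odorant = int(rng.integers(0, n))
        if added_variance is None:
            base_scale = float(
                np.median([np.median(np.diagonal(e.gamma)) for e in envs])
            )
            add = 100.0 * base_scale
        else:
            add = added_variance
        row = []
        for e in envs:
            k_before = _optimize(overlap_matrix(S, e), sigma2, Ktot, opt_options).K
            e_pert = perturb_single_variance(e, odorant, add)
            k_after = _optimize(overlap_matrix(S, e_pert), sigma2, Ktot, opt_options).K
            row.append(k_after - k_before)
        d1.append(row[0])
        d2.append(row[1])
    d1 = np.vstack(d1) if d1 else np.empty((0, S.n_receptors))
    d2 = np.vstack(d2) if d2 else np.empty((0, S.n_receptors))
    both = (np.abs(d1) > zero_tol) & (np.abs(d2) > zero_tol)
    n_both = int(both.sum())
    opp = float(np.sum(np.sign(d1[both]) != np.sign(d2[both]))) / max(n_both, 1)
    return ContextDependenceResult(d1, d2, opp, n_both, seed)


@dataclass(frozen=True)
class TuningSweepResult:
    widths: np.ndarray
    corr_log_snr: dict  # mean / p20 / p80 arrays over widths
    corr_inverse_diag: dict  # statistics of |corr|; sign reported separately
    inverse_diag_sign: np.ndarray  # mean sign of corr(Ka, sigma^2 (Q^-1)_aa)
    seed: int | None


def tuning_correlation_sweep(
    widths,
    n_receptors: int,
    n_odorants: int,
    env: OdorEnvironment,
    noise,
    Ktot: float,
    *,
    n_matrices_per_width: int = 24,
    seed: int | None = 0,
    opt_options: dict | None = None,
) -> TuningSweepResult:
    """Correlation of abundance with SNR and with the inverse-overlap diagonal.

    For each tuning width, ``n_matrices_per_width`` random sensing matrices
    are drawn on the fixed environment and optimized; the per-matrix Pearson
    correlations corr(Ka, log(Qaa/sigma_a^2)) and corr(Ka, sigma_a^2
    (Q^-1)_aa) are summarized by mean and 20th/80th percentiles.  The second
    correlation is negative (receptors whose signal is predictable from the
    others get fewer neurons); its magnitude is reported with the mean sign
    kept separately.  Matrices where Ka is constant across receptors yield an
    undefined correlation and are recorded as NaN.
    """
    widths = np.asarray(widths, dtype=float)
    if np.any((widths <= 0) | (widths > 1)):
        raise ValueError("widths must lie in (0, 1]")
    sigma2 = _as_sigma2(noise)
    rng = np.random.default_rng(seed)
    c_snr = np.full((widths.size, n_matrices_per_width), np.nan)
    c_inv = np.full((widths.size, n_matrices_per_width), np.nan)
    for i, w in enumerate(widths):
        for j in range(n_matrices_per_width):
            S = random_sensing_matrix(
                n_receptors, n_odorants, float(w), seed=int(rng.integers(0, 2**31))
            )
            Q = overlap_matrix(S, env)
            K = _optimize(Q, sigma2, Ktot, opt_options).K
            if np.ptp(K) == 0:
                continue
            log_snr = np.log(np.diagonal(Q) / sigma2)
            c_snr[i, j] = pearsonr(K, log_snr).statistic
            try:
                inv_diag = sigma2 * np.diagonal(np.linalg.inv(Q))
            except np.linalg.LinAlgError:
                continue
            c_inv[i, j] = pearsonr(K, inv_diag).statistic

    def _summary(vals, absolute=False):
        v = np.abs(vals) if absolute else vals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return {
                "mean": np.nanmean(v, axis=1),
                "p20": np.nanpercentile(v, 20, axis=1),
                "p80": np.nanpercentile(v, 80, axis=1),
            }

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sign = np.nanmean(np.sign(c_inv), axis=1)
    return TuningSweepResult(widths, _summary(c_snr), _summary(c_inv, absolute=True), sign, seed)


@dataclass(frozen=True)
class SubsamplingResult:
    removal_fraction: float
    mode: str
    correlations: np.ndarray
    mean: float
    p20: float
    p80: float
    seed: int | None


def subsampling_experiment(
    S: SensingMatrix,
    env: OdorEnvironment,
    noise,
    Ktot: float,
    removal_fraction: float,
    mode: str = "receptors",
    *,
    n_trials: int = 10,
    seed: int | None = 0,
    opt_options: dict | None = None,
) -> SubsamplingResult:
    """Robustness of predicted abundances to partial input knowledge.

    ``mode='receptors'`` removes a random fraction of receptor rows and
    correlates the retained receptors' re-optimized abundances with the
    full-information solution; ``mode='odorants'`` removes odorants from the
    environment and the matching sensing-matrix columns.  Returns the Pearson
    correlation per trial (exactly 1 when nothing is removed).
    """
    if not 0 <= removal_fraction < 1:
        raise ValueError("removal_fraction must be in [0, 1)")
    if mode not in ("receptors", "odorants"):
        raise ValueError("mode must be 'receptors' or 'odorants'")
    sigma2 = _as_sigma2(noise)
    m, n = S.n_receptors, S.n_odorants
    Q_full = overlap_matrix(S, env)
    K_full = _optimize(Q_full, sigma2, Ktot, opt_options).K
    if removal_fraction == 0.0:
        corr = np.ones(n_trials)
        return SubsamplingResult(removal_fraction, mode, corr, 1.0, 1.0, 1.0, seed)
    rng = np.random.default_rng(seed)
    corrs = np.empty(n_trials)
    for t in range(n_trials):
        if mode == "receptors":
            n_keep = m - int(round(removal_fraction * m))
            if n_keep < 2:
                raise ValueError("fewer than 2 receptors retained; lower removal_fraction")
            keep = np.sort(rng.choice(m, size=n_keep, replace=False))
            Q_sub = Q_full[np.ix_(keep, keep)]
            K_sub = _optimize(Q_sub, sigma2[keep], Ktot, opt_options).K
            ref = K_full[keep]
        else:
            n_keep = n - int(round(removal_fraction * n))
            if n_keep < 1:
                raise ValueError("no odorants retained; lower removal_fraction")
            keep = np.sort(rng.choice(n, size=n_keep, replace=False))
            env_sub = OdorEnvironment(
                env.c0[keep],
                env.gamma[np.ix_(keep, keep)],
                tuple(env.odorant_labels[i] for i in keep),
            )
            Q_sub = overlap_matrix(S.S[:, keep], env_sub)
            K_sub = _optimize(Q_sub, sigma2, Ktot, opt_options).K
            ref = K_full
        if np.ptp(K_sub) == 0 or np.ptp(ref) == 0:
            corrs[t] = np.nan
        else:
            corrs[t] = pearsonr(ref, K_sub).statistic
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return SubsamplingResult(
            removal_fraction,
            mode,
            corrs,
            float(np.nanmean(corrs)),
            float(np.nanpercentile(corrs, 20)),
            float(np.nanpercentile(corrs, 80)),
            seed,
        )


@dataclass(frozen=True)
class ExposureResult:
    baseline_K: np.ndarray  # median baseline abundance per receptor
    median_log_ratio: np.ndarray
    log_ratio_range: np.ndarray  # (M, 2) min-max over replicates
    zero_flag: np.ndarray  # True where K ~ 0 in some replicate (excluded from logs)
    range_vs_abundance_rank_corr: float
    n_replicates: int
    seed: int | None


def exposure_insilico(
    S: SensingMatrix,
    noise,
    Ktot: float,
    base_env: OdorEnvironment,
    perturbed_env: OdorEnvironment,
    *,
    n_jitter_replicates: int = 24,
    jitter_scale: float = 0.05,
    seed: int | None = 0,
    zero_tol: float | None = None,
    opt_options: dict | None = None,
) -> ExposureResult:
    """Per-receptor log-ratio of optimal abundances between two environments.

    Both covariances are re-jittered on their square roots for each replicate;
    the median log(K'/K) and its min-max range per receptor quantify both the
    predicted change and its robustness.  Receptors hitting zero abundance in
    any replicate are flagged and excluded from the log statistics rather than
    reported as -inf.  Rare receptors show wider ranges (negative rank
    correlation between baseline abundance and range width).
    """
    sigma2 = _as_sigma2(noise)
    m = S.n_receptors
    if zero_tol is None:
        zero_tol = 1e-6 * Ktot / m
    rng = np.random.default_rng(seed)
    base_k = np.full((n_jitter_replicates, m), np.nan)
    ratios = np.full((n_jitter_replicates, m), np.nan)
    zero_flag = np.zeros(m, dtype=bool)
    for r in range(n_jitter_replicates):
        if jitter_scale > 0:
            e1 = jitter_sqrt(base_env, jitter_scale, seed=int(rng.integers(0, 2**31)))
            e2 = jitter_sqrt(perturbed_env, jitter_scale, seed=int(rng.integers(0, 2**31)))
        else:
            e1, e2 = base_env, perturbed_env
        k1 = _optimize(overlap_matrix(S, e1), sigma2, Ktot, opt_options).K
        k2 = _optimize(overlap_matrix(S, e2), sigma2, Ktot, opt_options).K
        base_k[r] = k1
        ok = (k1 > zero_tol) & (k2 > zero_tol)
        zero_flag |= ~ok
        ratios[r, ok] = np.log(k2[ok] / k1[ok])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(ratios, axis=0)
        rng_lo = np.nanmin(ratios, axis=0)
        rng_hi = np.nanmax(ratios, axis=0)
        base_med = np.nanmedian(base_k, axis=0)
    width = rng_hi - rng_lo
    ok = np.isfinite(width) & np.isfinite(base_med) & ~zero_flag
    if ok.sum() >= 3 and np.unique(base_med[ok]).size > 1 and np.unique(width[ok]).size > 1:
        rho = float(spearmanr(base_med[ok], width[ok]).statistic)
    else:
        rho = float("nan")
    return ExposureResult(
        base_med,
        med,
        np.column_stack([rng_lo, rng_hi]),
        zero_flag,
        rho,
        n_jitter_replicates,
        seed,
    )
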