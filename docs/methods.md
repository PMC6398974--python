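# Methods

## Model

An olfactory scene is a vector of odorant concentrations `c ∈ R^N` drawn from
a Gaussian environment `c ~ N(c0, Γ)`.  A receptor repertoire is described by
a sensing matrix `S ∈ R^{M×N}`: `S_ai` is the expected response of a single
sensory neuron of receptor type `a` to unit concentration of odorant `i`.
With `K_a` neurons of type `a` converging on one glomerulus, the glomerular
response is modeled linearly as

    r_a = K_a Σ_i S_ai c_i + √K_a · η_a,      η_a ~ N(0, σ_a²).

The signal scales with the number of pooled neurons, and the pooled noise
standard deviation scales with √K_a (independent noise summed over K_a
neurons).  This scaling is the unique choice consistent with the
signal-to-noise matrix `K Σ⁻¹ Q` appearing in the information formula below,
and it makes the information invariant to splitting one receptor type's
neurons across several glomeruli (tested).

Under these Gaussian assumptions the mutual information between responses and
concentrations is

    I(r, c) = ½ Tr log(I + K Σ⁻¹ Q),      Q = S Γ Sᵀ,

with `K = diag(K_a)`, `Σ = diag(σ_a²)`.  `Q` (the *overlap matrix*) is the
covariance of noiseless glomerular signals; its diagonal over the noise
variances is the per-receptor squared SNR, and its off-diagonal structure is
what makes the optimal allocation *context dependent*.  The mean `c0` never
enters `Q` or `I`, so chronically present odors do not move the optimum
(asserted bitwise in tests).

The efficient-coding hypothesis is implemented as the constrained program

    maximize I(K)   subject to   Σ_a K_a = Ktot,  K_a ≥ 0,

treating abundances as real numbers.  `I` is concave in `K` (log-determinant
of an affine positive-semidefinite map), so the optimal value is unique and
Karush–Kuhn–Tucker (KKT) conditions are necessary and sufficient: the
information gradient `½[(Σ + QK)⁻¹Q]_aa` is constant (= μ) over expressed
receptor types and no larger than μ for unexpressed ones.

Analytic limits used as independent references:

* **Large populations** (`Ktot → ∞`): `K_a ≈ Ktot/M − (σ_a² A_aa − mean_b σ_b² A_bb)`
  with `A = Q⁻¹` — near-uniform, with deviations set by the noise-scaled
  diagonal of the inverse overlap matrix.  The raw formula can go negative for
  small budgets; it is returned unprojected by default with an optional
  simplex projection.
* **Small populations**: all neurons on `argmax_a Q_aa/σ_a²` (ties broken by
  lowest index).
* **Diagonal `Q`**: classic water-filling across parallel Gaussian channels;
  `Q = diag(2,1), σ² = 1, Ktot = 10` gives `K = (5.25, 4.75)` exactly.

## Optimizer

`optimal_distribution` runs SLSQP on the normalized variables `x = K/Ktot`
(analytic gradient, `ftol = 1e-14`), then refines with an equality-constrained
active-set Newton method: the Hessian of `I` is `−½ (W ∘ Wᵀ)` with
`W = (Σ + QK)⁻¹ Q`, so Newton steps on the reduced KKT system converge
quadratically.  Receptors pushed below zero are dropped from the active set;
inactive receptors whose gradient exceeds μ are re-added.  In practice the
polish reaches KKT residuals near machine precision, which is what allows the
closed-form water-filling solution to be reproduced to better than 1e−6 in
`K` itself.

Concavity means restarts are not needed for correctness; the default of five
Dirichlet restarts plus the uniform start is kept as cheap insurance and the
experiment drivers use a single start for speed.  Non-convergence (KKT
residual above `tol`, default 1e−6 relative) is flagged on the result and
warned about, never silent.

The KKT residual of a feasible allocation is computed as
`max(spread of gradient over active set, worst positive excess over inactive
set) / μ̂`, with the active set at `K_a > 1e-6·Ktot/M` by default.

`receptor_count_curve` counts receptors with `K_a > 1e-3 · Ktot/M` as
expressed; 1e−3 separates the numerically-zero cluster from the plateaus of
the step-transition curve.

## Birth/death dynamics

Receptor abundances evolve by

    dK_a/dt = α { K_a − λ K_a² − σ_a² (R⁻¹)_aa K_a² },

with `R = diag(K) Q diag(K) + diag(K σ²)` the response covariance at the
current abundances.  Birth (`+K_a`) is experience independent; the
density-dependent death term `λK_a²` caps the total near `M/λ`; the
experience term modulates death through the inverse response covariance.
Without it the dynamics are logistic with fixed point `K_a = 1/λ`.  At any
interior fixed point the information gradient equals `λ/2` uniformly, i.e.
the endpoint satisfies the KKT conditions of the constrained problem at the
emergent total `Σ K_a` — convergence of the dynamics to the efficient-coding
optimum is therefore checked against the independent optimizer in tests.

Numerics: explicit Euler with `dt = 0.01/α` by default, halving the step when
an update would overshoot below `−noise_floor`, and clipping at zero (the
zero state is invariant: the rate vanishes as `K_a → 0`, which is also why
scarce receptor types converge slowest).  The experience term is evaluated
through the factorization `σ_a²(R⁻¹)_aa K_a² = σ_a² K_a [(Q diag(K)+Σ)⁻¹]_aa`,
which is exact for `K_a > 0`, remains finite at `K_a = 0` where `R` itself is
singular, and avoids any pseudo-inverse fallback; the equivalence with the
direct `R⁻¹` expression is tested.  A `cache_steps` option recomputes the
term every few steps for speed; trajectories are logged on a log-spaced time
grid.

## Synthetic ensembles

* **Environments**: `Γ = D^{1/2} C D^{1/2}` with `C = normalize(GGᵀ)`,
  `G ∈ R^{N×⌈βN⌉}` standard normal, and lognormal(μ=0, σ_ln=1) variances in
  `D`.  `β` (default 8) tunes correlation strength: more columns average the
  off-diagonal correlations toward zero.  `c0 = 0` by default (it is
  irrelevant to the optimum).
* **Perturbations**: adding variance to one odorant (`Γ + v e_i e_iᵀ`, a
  PSD rank-1 update) or to a set of 10; the default added variance is 100×
  the median base variance, large enough to dominate the base scale.
* **Non-overlapping pairs**: odorants are randomly split in halves; each
  environment keeps the generic structure on its half and is damped to a
  floor variance (1e−4 × median generic variance) on the other, so every
  odorant is salient in at most one environment.
* **Square-root jitter**: `Γ' = (Γ^{1/2} + εZ)(Γ^{1/2} + εZ)ᵀ` — PSD by
  construction, with first-order distance linear in ε.
* **Sensing matrices**: each receptor row gets `round(width·N)` strong
  entries (lognormal(0, 0.5) magnitudes, non-negative) at random positions
  and weak entries elsewhere (same distribution × 0.02).  Wider tuning
  produces more correlated noiseless responses.

What the generators do *not* emulate: sparse (mixture-like) olfactory scenes,
measured receptor affinities, temporal structure, or integer neuron counts.
Passing tests therefore demonstrate the model's internal consistency and its
qualitative phenomenology on Gaussian ensembles, not quantitative agreement
with any measured repertoire.

## Experiment drivers and problem sizes

The drivers default to single-start optimization (valid by concavity) and the
following desk-scale sizes, chosen so the full suite and the acceptance
script each run in well under a minute while keeping ensemble statistics
stable: 50 environment pairs per ΔK ensemble (fly-shaped 24×110 sensing
matrix, `Ktot = 25 000`), 20 pairs for context dependence (`Ktot = 2000`),
12 sensing matrices per tuning width, 8 subsampling trials, and 12 jitter
replicates for the 59-receptor exposure run.  ΔK summary fractions are
reported at cuts 0.1, 50, 800, and 20% of the mean abundance `Ktot/M`.
Zero-abundance receptors are excluded from log-ratio statistics and flagged
rather than reported as −∞.

**Noise scale.**  The per-neuron noise variance is the one model parameter
with no canonical unit once the sensing matrix is synthetic.  The experiment
suite fixes it by regime rather than by value: σ² is chosen so that the
pooled per-receptor SNR at the uniform allocation, `(Ktot/M)·median(Q_aa)/σ²`,
is ≈ 5 — the intermediate-noise regime the theory targets, in which noise
matters but does not overwhelm the signal and a minority of receptor types
sit at zero abundance.  With σ² fixed at 1 instead, the same budgets land in
the deep high-SNR regime where all allocations are near-uniform and
environment changes have vanishing effect.

## Known limitations

* The optimizer's active-set polish assumes a well-conditioned reduced
  Hessian; exactly duplicated receptor rows make the optimum non-unique (in
  `K`, not in `I`), and the symmetric equal-split solution is returned from
  the uniform start.  Tests compare `I`, not `K`, for such degenerate cases.
* Explicit Euler is first-order; endpoint accuracy, not path accuracy, is the
  design goal for the dynamics.
* The grid-search oracle used in tests is exhaustive only for M ∈ {2, 3}
  (closed-form 2×2/3×3 determinants vectorized over the simplex grid).
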