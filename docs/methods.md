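# Methods

## Model

`bagmix` fits a finite mixture of linear regressions to balanced
longitudinal data. Subject *i* = 1..N is observed at occasions
*t* = 1..T; each observation carries a latent state label
S_it ∈ {1..S} with P(S_it = s) = q_s, i.i.d. across observations.
Conditional on S_it = s,

    y_it = x_it θ_s + u_i + ε_it,    ε_it ~ N(0, σ_ε²),  u_i ~ N(0, σ_u²),

where θ_s = (α_s, β_s) stacks L ungrouped coefficients and p grouped
coefficients partitioned into J groups G_1..G_J of sizes p_1..p_J, and
u_i is a subject random intercept. S is known and fixed.

**Collapsed random effects.** Inference runs on the collapsed model in
which the marginal error covariance Σ + ZDZᵀ is approximated by
σ*²I: the random intercept is absorbed into a single state-specific
error variance σ_s² and is never sampled. The generator keeps u_i in
the data so the cost of this approximation is measurable (see
*Limitations*). Under the reference design (σ_u² = σ_ε² = 1) the fitted
σ_s² concentrates near 2, as expected.

**Shrinkage priors.** Coefficients carry conditional Laplace priors —
componentwise adaptive-lasso shrinkage on α, adaptive *group*-lasso
shrinkage on each β_Gj with norm metric K_j = p_j I. Expressed as
normal scale mixtures, the hierarchy per state is

    α | σ², τ_α²      ~ N_L(0, σ² diag(τ_α1², .., τ_αL²))
    τ_αl² | λ_l²      ~ Exp(rate λ_l²/2)
    β_Gj | σ², τ_Gj²  ~ N_pj(0, σ² τ_Gj² K_j⁻¹)
    τ_Gj² | γ_j²      ~ Gamma((p_j+1)/2, rate γ_j²/2)
    σ²                ~ InvGamma(a, b)
    λ_l²              ~ Gamma(a_λ, rate b_λ)
    γ_j²              ~ Gamma(a_γ, rate b_γ)

All Gamma distributions in code and docs are rate-parameterized.

## Gibbs sampler

One iteration: (1) for each state, a Gauss–Seidel sweep of the full
conditionals over the observations currently assigned to it, in the
fixed order α; β_G1..β_GJ; σ⁻²; τ_α⁻²; τ_G⁻²; λ²; γ²; (2) every
observation's state redrawn from its categorical posterior
q_s N(y_it; x_itθ_s, σ_s²), normalized in log space with
max-subtraction; (3) q set to the empirical assignment proportions.

The conditionals are conjugate:

* α | · ~ N(A⁻¹X_αᵀY_α, σ²A⁻¹), A = X_αᵀX_α + Σ_α⁻¹, with Y_α the
  partial residual removing the grouped block; sampled via Cholesky of A.
* β_Gj | · ~ N(B⁻¹X_GjᵀY_Gj, σ²B⁻¹), B = X_GjᵀX_Gj + τ_Gj⁻²K_j, with
  Y_Gj the partial residual excluding group j.
* σ⁻² | · ~ Gamma(a + (n_s + L + p)/2, b + ½[‖Y − Xθ‖² + αᵀΣ_α⁻¹α +
  Σ_j τ_Gj⁻² β_GjᵀK_jβ_Gj]), n_s the state's current observation
  count. The prior-shape term `a` and the ½ on each quadratic form are
  required for the conditional to integrate correctly against the
  normal hierarchy; the successive-conditional joint test below fails
  without them.
* τ_αl⁻² | · ~ InverseGaussian(mean √(λ_l²σ²/α_l²), shape λ_l²), and
  τ_Gj⁻² | · analogously with ‖β_Gj‖²_K = p_j β_Gjᵀβ_Gj. These are the
  standard conjugate updates under the scale-mixture representation; a
  Gamma with those parameters would not be a conjugate update.
* λ_l² | · ~ Gamma(a_λ + 1, b_λ + τ_αl²/2);
  γ_j² | · ~ Gamma(a_γ + (p_j+1)/2, b_γ + τ_Gj²/2). With p_j = 1 the
  group update degenerates to the adaptive-lasso form.

Inverse-Gaussian draws use the Michael–Schucany–Haas transformation,
vectorized; its output is KS-tested against an independent CDF.

**Numerical choices.** |α_l| and ‖β_Gj‖_K are floored at 1e-10 before
computing the IG mean (which diverges at zero); a clamp logs a warning
and preserves the heavy-shrinkage regime without NaN. A state left
empty by a reassignment step has its block refreshed from the prior for
that iteration (logged, not fatal) — transient emptiness is routine
early in mixture MCMC. Draws are recorded every iteration; the
default run is 5000 iterations with the first 2500 discarded.

**q update.** The printed algorithm sets q to the empirical assignment
proportions; that is the default. A conjugate Dirichlet(1 + counts)
draw is available behind `ChainConfig(q_update="dirichlet")` for
sensitivity checks; on the reference design the two are
indistinguishable in the summaries.

**Label switching.** The mixture posterior is invariant under
permutation of state labels. `relabel_states` permutes each iteration's
labels toward the running per-state mean of θ (online k-means style,
deterministic given the draws), then aligns chains to a common
reference; an explicit ordering constraint is deliberately avoided. In
the replication harness, recovered states are matched to simulation
truth per replication by Hungarian assignment on the confusion matrix
of posterior-mode states.

## Variable selection

Equal-tailed posterior intervals at level 0.95 (HPD available as an
option). An α component is kept iff its interval excludes zero. A group
is kept iff **every** component's interval excludes zero — one
straddling component eliminates the whole group. The strict rule is
deliberate: a group with truth (0.6, 0, −1.1) is *dropped* because of
its zero middle component. The alternative reading (drop only when all
components straddle zero) would keep that group and changes the
correct/incorrect-zero bookkeeping entirely. Point estimates are
posterior means. Selection is one-pass; no re-fit after elimination.

## Convergence monitoring

EPSR is the standard Gelman–Rubin potential scale reduction
√(((n−1)/n·W + B/n)/W) without rank-normalization, computed on the
second half of the monitored window across ≥2 chains started from
dispersed (prior-drawn) initializations. Monitored parameters: every
α and β component and σ² per state (penalty parameters λ², γ² can be
added via `include_scales`). Values below 1.2 are taken as converged;
on the reference design three chains sit below 1.05 by iteration 2000.

## Synthetic-data generator

`two_state_design(n)` fixes the reference conditions used throughout
validation: T = 3; S = 2 with q = (0.5, 0.5); L = 2 ungrouped
covariates ~ N(0, I); three groups of three covariates with AR-type
within-group correlation ρ_j^|i−k|, ρ = (0.7, 0.6, 0.4); state-1 truth
α = (−1.7, 1.3), β_G1 = (2.0, −0.4, 1.3), β_G2 = (0.6, 0, −1.1),
β_G3 = 0; state-2 truth α = (0.3, −1.2), β_G1 = β_G2 = 0,
β_G3 = (−1.5, 2.2, 0.5); σ_u² = σ_ε² = 1. States are drawn per
observation (i, t); `state_per_subject=True` holds a subject in one
state, and `intercept=True` prepends a constant column, matching the
structure of observational case studies (e.g. a J = 4 grouping of
clinical covariates with an intercept).

What the generator does *not* emulate: binary/bounded covariates,
missing occasions (balanced panels only), covariate distributions of
any real cohort. Passing tests therefore demonstrate correctness of
the algorithm under Gaussian designs, not performance on real data.

## Problem sizes used in validation

The replication harness runs R = 25 replications at n = 100 (5000
iterations, one chain per fit) and a reduced R = 5 at n = 300;
convergence checks use 3 chains × 2000 iterations. These sizes were
chosen so the whole suite completes on a single CPU while keeping
Monte-Carlo error interpretable; R = 100 reproduces the full study via
`replicate(..., R=100)` or the `bagmix replicate` command.

## Known limitations

* **Separation at the reference noise level.** With the random
  intercept collapsed, per-observation noise variance is 2 and the
  Bayes-optimal assignment accuracy under the reference design is
  ≈ 0.83 (computable from the true parameters; the fitted sampler
  matches it to within a point). The resulting soft-assignment errors
  attenuate the large coefficients of state-specific groups and
  inflate their RMSE relative to a single-regression fit of the same
  size. Consequently the weak β_G1 component (−0.4, oracle SE ≈ 0.2 at
  n = 100) frequently has an interval covering zero, and the strict
  rule then drops G1: group retention for G1 in state 1 is a minority
  outcome at n = 100 and only becomes reliable at n = 300. This is a
  property of the design/noise combination, not of the sampler — the
  oracle bounds above are computed alongside the tests.
* The collapse discards within-subject correlation (u_i shared across
  T occasions); comparison runs with i.i.d. noise of the same total
  variance show this costs little additional estimation error at T = 3.
* Unbalanced panels and missing data are out of scope (complete cases
  only). S is fixed and known; no model choice over the state count.
* States are exchangeable i.i.d. labels; no Markov dependence over t.
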