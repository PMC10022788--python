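# bagmix — Bayesian adaptive group lasso for hidden-state mixed regression

`bagmix` is a Python library for variable selection and estimation in
mixed linear regression models whose observations come from a small
number of *hidden states*. It targets longitudinal biostatistics
settings — repeated clinical measurements where the population splits
into latent subgroups (say, impaired vs. unimpaired cognition) and a
covariate can matter in one subgroup but not the other — and
statisticians who want a fully Bayesian, group-structured shrinkage
treatment of that problem with reproducible MCMC.

## Model

For subject *i* at occasion *t*, conditional on the latent label
S_it = s (P(S_it = s) = q_s, i.i.d.):

    y_it = x_it θ_s + u_i + ε_it,     ε_it ~ N(0, σ_ε²),  u_i ~ N(0, σ_u²)

θ_s = (α_s, β_s) stacks L ungrouped coefficients and J groups of
grouped coefficients β_G1..β_GJ. Shrinkage comes from an adaptive
(group) lasso penalty, i.e. conditional Laplace priors

    p(α|σ²) ∝ ∏_l exp(−λ_l|α_l|/σ),   p(β|σ²) ∝ ∏_j exp(−γ_j‖β_Gj‖_{K_j}/σ),

with K_j = p_j I, written as normal scale mixtures so that every full
conditional is conjugate and the model is estimated by Gibbs sampling
on the collapsed likelihood (random intercept absorbed into a
state-specific error variance). Variable selection uses the 95%
credible-interval criterion: an α component survives if its interval
excludes zero; a group survives only if *every* component's interval
excludes zero. Convergence is monitored by EPSR (Gelman–Rubin) across
dispersed chains. See `docs/methods.md` for the full hierarchy,
conditionals, and design choices.

## Worked example

```python
from bagmix import (two_state_design, simulate, Hyperparameters,
                    ChainConfig, run_chain, relabel_states, select)
from bagmix.diagnostics import match_states_to_truth

design = two_state_design(n=100)          # 2 states, L=2, 3 groups of 3
data = simulate(design, rng=7)            # N=100, T=3 -> 300 rows
chain = run_chain(data, S=2, hyperparams=Hyperparameters.default(),
                  chain_config=ChainConfig(n_iter=5000, burn_in=2500, seed=7))
relabel_states([chain])
match_states_to_truth(chain, data.true_states)
result = select(chain, design.structure.group_slices)
```

Running `python examples/01_simulate_and_fit.py` (the same pipeline)
prints:

```
state 1:
  posterior mean theta: [-1.61  1.28  1.93 -0.56  1.46  0.56 -0.31 -0.88  0.02  0.04 -0.09]
  true theta:           [-1.7  1.3  2.  -0.4  1.3  0.6  0.  -1.1  0.   0.   0. ]
  sigma2 (collapsed):   2.76 (true random-intercept + error variance = 2)

state 2:
  posterior mean theta: [ 0.28 -1.2   0.07  0.06  0.07  0.04  0.03  0.1  -1.3   2.08  0.67]
  true theta:           [ 0.3 -1.2  0.   0.   0.   0.   0.   0.  -1.5  2.2  0.5]
  sigma2 (collapsed):   2.25 (true random-intercept + error variance = 2)

state-assignment accuracy vs truth: 0.847
```

Each state's regression is recovered from unlabeled observations: the
large coefficients land near truth, the all-zero groups are shrunk to
≈0, the collapsed error variance sits near σ_u² + σ_ε² = 2, and 85% of
observations are assigned to the correct hidden state — essentially the
Bayes-optimal rate under this noise level (≈0.83, computable from the
true parameters). `examples/02_variable_selection.py` then shows the
strict group rule at work: in state 1 the interval of the weak β_G1
component (truth −0.4) covers zero, so the whole G1 group is dropped
there, while state 2's signal group G3 is kept with every interval
clear of zero.

Other entry points: `examples/03_convergence_epsr.py` (EPSR table over
three dispersed chains), `examples/04_replication_study.py`
(bias/RMSE and selection frequencies over repeated fits), and a thin
CLI (`bagmix simulate|fit|select|diagnose|replicate --help`) that works
on plain CSV/JSON/YAML files and writes a reproducibility manifest per
run; ready-made hyperparameter files live in `examples/configs/`
(`prior_default.yaml`, `prior_alternative.yaml`).

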