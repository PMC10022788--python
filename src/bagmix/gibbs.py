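"""Gibbs sampler driver: per-state parameter sweeps, latent-state
reallocation, mixing-weight updates, multi-chain orchestration and
post-hoc relabeling.

One iteration = (i) for every state s, a Gauss–Seidel sweep of all full
conditionals on the observations currently assigned to s; (ii) each
observation's state redrawn from its categorical posterior
q_s p_s(y|x, zeta_s) / sum_s' q_s' p_s'(y|x, zeta_s'); (iii) mixing
weights updated to the empirical assignment proportions.  A state left
with no observations has its parameters refreshed from the prior for that
iteration (with a logged warning) rather than aborting — transient
emptiness is routine early in mixture MCMC.

Because the mixture posterior is invariant under permutation of state
labels, chains are summarized only after :func:`relabel_states`, which
permutes labels iteration-by-iteration toward the running per-state mean
of theta, then aligns chains to a common reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import conditionals
from .model import Dataset, Hyperparameters, MixtureState, StateParameters

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run configuration.

    ``init_mode`` is ``"default"`` (coefficients 0, scales 1) or
    ``"prior"`` (dispersed starts drawn from the hierarchical prior, as
    needed for multi-chain convergence monitoring).  ``q_update`` is
    ``"empirical"`` (assignment proportions) or ``"dirichlet"``
    (conjugate Dirichlet(1 + counts) draw, for sensitivity checks).
    """

    n_iter: int = 5000
    burn_in: int = 2500
    n_chains: int = 1
    seed: int = 0
    init_mode: str = "default"
    q_update: str = "empirical"

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError(
                f"need 0 < burn_in < n_iter, got burn_in={self.burn_in}, n_iter={self.n_iter}"
            )
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.init_mode not in ("default", "prior"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.q_update not in ("empirical", "dirichlet"):
            raise ValueError(f"unknown q_update {self.q_update!r}")


@dataclass
class ChainResult:
    """All draws of one chain, one slot per iteration (burn-in included).

    Array shapes: alpha (n_iter, S, L), beta (n_iter, S, p), sigma2 /
    q (n_iter, S), lambda2 / tau_alpha2 (n_iter, S, L), gamma2 /
    tau_group2 (n_iter, S, J), assignments (n_iter, N*T) with 1-based
    labels.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray
    lambda2: np.ndarray
    gamma2: np.ndarray
    tau_alpha2: np.ndarray
    tau_group2: np.ndarray
    q: np.ndarray
    assignments: np.ndarray
    config: ChainConfig
    seed_sequence: tuple[int, ...] = ()

    @property
    def n_iter(self) -> int:
        return self.alpha.shape[0]

    @property
    def S(self) -> int:
        return self.alpha.shape[1]

    def theta(self) -> np.ndarray:
        """(n_iter, S, L+p) stacked coefficient draws."""
        return np.concatenate([self.alpha, self.beta], axis=2)

    def post_burnin(self) -> "ChainResult":
        """View of the draws after discarding the burn-in slice."""
        b = self.config.burn_in
        return ChainResult(
            alpha=self.alpha[b:],
            beta=self.beta[b:],
            sigma2=self.sigma2[b:],
            lambda2=self.lambda2[b:],
            gamma2=self.gamma2[b:],
            tau_alpha2=self.tau_alpha2[b:],
            tau_group2=self.tau_group2[b:],
            q=self.q[b:],
            assignments=self.assignments[b:],
            config=replace(self.config, burn_in=1, n_iter=self.n_iter - b + 2)
            if self.n_iter - b <= 1
            else replace(self.config, burn_in=1, n_iter=self.n_iter - b),
            seed_sequence=self.seed_sequence,
        )

    def posterior_mean_theta(self) -> np.ndarray:
        """(S, L+p) posterior means of the post-burn-in coefficient draws."""
        return self.post_burnin().theta().mean(axis=0)

    def modal_states(self) -> np.ndarray:
        """Per-observation posterior-mode state over post-burn-in draws."""
        a = self.post_burnin().assignments
        counts = np.stack([(a == s + 1).sum(axis=0) for s in range(self.S)])
        return counts.argmax(axis=0) + 1

    def _apply_permutation(self, k: int, perm: tuple[int, ...]) -> None:
        """In-place relabel of iteration k: new state i <- old state perm[i]."""
        idx = list(perm)
        for arr in (
            self.alpha,
            self.beta,
            self.sigma2,
            self.lambda2,
            self.gamma2,
            self.tau_alpha2,
            self.tau_group2,
            self.q,
        ):
            arr[k] = arr[k][idx]
        inv = np.empty(len(idx), dtype=self.assignments.dtype)
        for new, old in enumerate(idx):
            inv[old] = new + 1
        self.assignments[k] = inv[self.assignments[k] - 1]


def initialize(
    dataset: Dataset,
    S: int,
    hyperparams: Hyperparameters,
    rng: np.random.Generator,
    init_mode: str = "default",
) -> MixtureState:
    """Starting MixtureState: uniform random assignments, q = 1/S.

    ``init_mode="default"`` starts coefficients at zero with unit scales;
    ``"prior"`` draws every block from the hierarchical prior so that
    repeated calls give dispersed starting points.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if S > dataset.n_obs:
        raise ValueError(f"S={S} exceeds the number of observations {dataset.n_obs}")
    structure = dataset.structure
    assignments = rng.integers(1, S + 1, size=dataset.n_obs)
    if init_mode == "default":
        params = [StateParameters.initial(structure) for _ in range(S)]
    elif init_mode == "prior":
        params = [
            conditionals.sample_prior_params(
                structure.L, structure.group_sizes, hyperparams, rng
            )
            for _ in range(S)
        ]
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    return MixtureState(S=S, params=params, q=np.full(S, 1.0 / S), assignments=assignments)


def _log_lik_matrix(dataset: Dataset, params: list[StateParameters]) -> np.ndarray:
    """(N*T, S) matrix of per-observation Gaussian log-likelihoods."""
    X = np.hstack([dataset.X_alpha, dataset.X_beta])
    cols = []
    for sp in params:
        resid = dataset.y - X @ sp.theta
        cols.append(-0.5 * (_LOG_2PI + np.log(sp.sigma2) + resid * resid / sp.sigma2))
    return np.stack(cols, axis=1)


def state_posterior(
    y_it: float,
    x_it: np.ndarray,
    mixture: MixtureState,
    q: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior state probabilities of one observation,
    q_s N(y; x theta_s, sigma_s^2) normalized over s, in log space."""
    q = mixture.q if q is None else np.asarray(q, dtype=float)
    x = np.ravel(x_it)
    with np.errstate(divide="ignore"):
        logp = np.log(q)
    for s, sp in enumerate(mixture.params):
        resid = float(y_it) - float(x @ sp.theta)
        logp[s] += -0.5 * (_LOG_2PI + np.log(sp.sigma2) + resid * resid / sp.sigma2)
    m = logp.max()
    if not np.isfinite(m):
        raise FloatingPointError("all state likelihoods vanished for observation")
    w = np.exp(logp - m)
    return w / w.sum()


def _state_posterior_all(
    dataset: Dataset, params: list[StateParameters], q: np.ndarray
) -> np.ndarray:
    """(N*T, S) posterior state probabilities, log-space, max-subtracted."""
    logp = _log_lik_matrix(dataset, params)
    with np.errstate(divide="ignore"):
        logp = logp + np.log(q)[None, :]
    m = logp.max(axis=1, keepdims=True)
    bad = ~np.isfinite(m).ravel()
    if bad.any():
        raise FloatingPointError(
            f"all state likelihoods vanished at observation index {int(np.flatnonzero(bad)[0])}"
        )
    w = np.exp(logp - m)
    return w / w.sum(axis=1, keepdims=True)


def sample_states(
    dataset: Dataset, mixture: MixtureState, rng: np.random.Generator
) -> np.ndarray:
    """Redraw every S_it from its categorical posterior via inverse-CDF on
    one U(0,1) draw per observation."""
    probs = _state_posterior_all(dataset, mixture.params, mixture.q)
    return _draw_categorical(probs, rng)


def _draw_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=probs.shape[0])
    return (u[:, None] > cum).sum(axis=1).astype(np.int64) + 1


def update_q(assignments: np.ndarray, S: int) -> np.ndarray:
    """Empirical assignment proportions q_s = #{S_it = s} / (N*T)."""
    assignments = np.asarray(assignments)
    if assignments.size == 0:
        raise ValueError("assignments must be nonempty")
    counts = np.bincount(assignments - 1, minlength=S)[:S]
    return counts / assignments.size


def run_chain(
    dataset: Dataset,
    S: int,
    hyperparams: Hyperparameters,
    chain_config: ChainConfig,
    rng: np.random.Generator | None = None,
) -> ChainResult:
    """Run one chain for ``n_iter`` iterations, recording every draw."""
    cfg = chain_config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    structure = dataset.structure
    L, p, J, n_obs = structure.L, structure.p, structure.J, dataset.n_obs

    mixture = initialize(dataset, S, hyperparams, rng, cfg.init_mode)
    out = ChainResult(
        alpha=np.empty((cfg.n_iter, S, L)),
        beta=np.empty((cfg.n_iter, S, p)),
        sigma2=np.empty((cfg.n_iter, S)),
        lambda2=np.empty((cfg.n_iter, S, L)),
        gamma2=np.empty((cfg.n_iter, S, J)),
        tau_alpha2=np.empty((cfg.n_iter, S, L)),
        tau_group2=np.empty((cfg.n_iter, S, J)),
        q=np.empty((cfg.n_iter, S)),
        assignments=np.empty((cfg.n_iter, n_obs), dtype=np.int16),
        config=cfg,
    )

    for k in range(cfg.n_iter):
        for s in range(1, S + 1):
            sp = mixture.params[s - 1]
            n_s = int(np.count_nonzero(mixture.assignments == s))
            if n_s == 0:
                logger.warning("state %d empty at iteration %d; prior refresh", s, k)
                mixture.params[s - 1] = conditionals.sample_prior_params(
                    L, structure.group_sizes, hyperparams, rng
                )
                continue
            ctx = conditionals.ConditionalContext.for_state(
                dataset, sp, hyperparams, mixture.assignments, s, rng
            )
            conditionals.sweep_state(ctx)
        mixture.assignments = sample_states(dataset, mixture, rng)
        if cfg.q_update == "empirical":
            mixture.q = update_q(mixture.assignments, S)
        else:
            counts = np.bincount(mixture.assignments - 1, minlength=S)[:S]
            mixture.q = rng.dirichlet(1.0 + counts)

        for s in range(S):
            sp = mixture.params[s]
            out.alpha[k, s] = sp.alpha
            out.beta[k, s] = sp.beta
            out.sigma2[k, s] = sp.sigma2
            out.lambda2[k, s] = sp.lambda2
            out.gamma2[k, s] = sp.gamma2
            out.tau_alpha2[k, s] = sp.tau_alpha2
            out.tau_group2[k, s] = sp.tau_group2
        out.q[k] = mixture.q
        out.assignments[k] = mixture.assignments
    return out


def run_chains(
    dataset: Dataset,
    S: int,
    hyperparams: Hyperparameters,
    chain_config: ChainConfig,
) -> list[ChainResult]:
    """Run ``n_chains`` independent chains with seeds spawned from the
    master seed, then relabel/align them (no-op for S = 1)."""
    results = []
    for c in range(chain_config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([chain_config.seed, c]))
        res = run_chain(dataset, S, hyperparams, chain_config, rng=rng)
        res.seed_sequence = (chain_config.seed, c)
        results.append(res)
    if S >= 2:
        results = relabel_states(results)
    return results


def relabel_states(chain_results: list[ChainResult]) -> list[ChainResult]:
    """Resolve label switching within and across chains.

    Within each chain, iteration k's labels are permuted to minimize the
    squared distance between its per-state theta vectors and the running
    per-state mean of the already-relabeled draws (online k-means-style).
    Chains after the first are then aligned to the first chain's
    post-burn-in mean by one global permutation.  Deterministic given the
    draws; mutates and returns the inputs.
    """
    if not chain_results:
        return chain_results
    S = chain_results[0].S
    perms = list(itertools.permutations(range(S)))
    reference: np.ndarray | None = None
    for chain in chain_results:
        theta = chain.theta()
        if reference is None:
            running = theta[0].copy()
            count = 1
            start = 1
        else:
            running = reference.copy()
            count = 50  # damp the cross-chain anchor so early draws cannot drag it
            start = 0
        for k in range(start, chain.n_iter):
            best, best_cost = perms[0], np.inf
            for perm in perms:
                cost = float(((theta[k, list(perm)] - running) ** 2).sum())
                if cost < best_cost:
                    best, best_cost = perm, cost
            if best != perms[0]:
                chain._apply_permutation(k, best)
                theta[k] = theta[k, list(best)]
            running += (theta[k] - running) / (count + 1)
            count += 1
        if reference is None:
            reference = chain.posterior_mean_theta()
    return chain_results
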