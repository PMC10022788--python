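"""Full conditional posterior samplers for the Gibbs sweep.

Each sampler draws one parameter block given the rows of the dataset
currently assigned to one hidden state and the freshest values of every
other block.  All Gamma distributions are rate-parameterized.  The latent
scale updates for tau^-2 are Inverse-Gaussian draws, the standard conjugate
update under the normal/exponential (and normal/gamma, for groups)
scale-mixture representation of the Laplace prior: with

    alpha_l | sigma^2, tau_al^2 ~ N(0, sigma^2 tau_al^2),
    tau_al^2 | lambda_l^2      ~ Exp(rate = lambda_l^2 / 2),

the conditional of tau_al^-2 is IG(mean = sqrt(lambda_l^2 sigma^2 /
alpha_l^2), shape = lambda_l^2), and analogously for the group scales with
the K_j-norm ||beta_Gj||_K^2 = p_j beta_Gj' beta_Gj in place of alpha_l^2.

Coefficient magnitudes are floored at ``MAGNITUDE_FLOOR`` before computing
the IG mean, which diverges at exactly zero; a clamp is logged, not raised,
because transient near-zero draws are routine under heavy shrinkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .model import Dataset, Hyperparameters, StateParameters

logger = logging.getLogger(__name__)

#: lower clamp on |alpha_l| and ||beta_Gj||_K before inverting in the IG mean
MAGNITUDE_FLOOR = 1e-10


def sample_inverse_gaussian(
    rng: np.random.Generator,
    mean: np.ndarray | float,
    shape: np.ndarray | float,
) -> np.ndarray:
    """Vectorized Inverse-Gaussian(mean mu, shape lam) draws.

    Michael–Schucany–Haas transformation: one chi-square and one uniform
    per draw.  Density  sqrt(lam/(2 pi x^3)) exp(-lam (x-mu)^2 / (2 mu^2 x)).
    """
    mu = np.asarray(mean, dtype=float)
    lam = np.asarray(shape, dtype=float)
    mu, lam = np.broadcast_arrays(mu, lam)
    if np.any(mu <= 0) or np.any(lam <= 0):
        raise ValueError("inverse-Gaussian mean and shape must be > 0")
    nu = rng.standard_normal(mu.shape)
    w = nu * nu
    # smaller root of the quadratic in x/mu
    x = mu + mu * mu * w / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    u = rng.uniform(size=mu.shape)
    take_other = u > mu / (mu + x)
    out = np.where(take_other, mu * mu / x, x)
    return out


@dataclass
class ConditionalContext:
    """Rows of one state plus its current parameter block.

    ``X_alpha``, ``X_beta``, ``y`` contain only the observations currently
    assigned to the state being updated.
    """

    X_alpha: np.ndarray
    X_beta: np.ndarray
    y: np.ndarray
    params: StateParameters
    hyper: Hyperparameters
    rng: np.random.Generator
    group_slices: list[slice]
    group_sizes: tuple[int, ...]

    @classmethod
    def for_state(
        cls,
        dataset: Dataset,
        params: StateParameters,
        hyper: Hyperparameters,
        assignments: np.ndarray,
        state_id: int,
        rng: np.random.Generator,
    ) -> "ConditionalContext":
        mask = np.asarray(assignments) == state_id
        return cls(
            X_alpha=dataset.X_alpha[mask],
            X_beta=dataset.X_beta[mask],
            y=dataset.y[mask],
            params=params,
            hyper=hyper,
            rng=rng,
            group_slices=dataset.structure.group_slices,
            group_sizes=dataset.structure.group_sizes,
        )

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]


def sample_lambda2(l: int, ctx: ConditionalContext) -> float:
    """lambda_l^2 | . ~ Gamma(a_lambda + 1, rate = b_lambda + tau_al^2 / 2)."""
    tau2 = ctx.params.tau_alpha2[l]
    if not tau2 > 0:
        raise ValueError(f"tau_alpha2[{l}] must be > 0, got {tau2}")
    shape = ctx.hyper.a_lambda + 1.0
    rate = ctx.hyper.b_lambda + 0.5 * tau2
    return float(ctx.rng.gamma(shape, 1.0 / rate))


def sample_gamma2(j: int, ctx: ConditionalContext) -> float:
    """gamma_j^2 | . ~ Gamma(a_gamma + (p_j+1)/2, rate = b_gamma + tau_Gj^2/2)."""
    tau2 = ctx.params.tau_group2[j]
    if not tau2 > 0:
        raise ValueError(f"tau_group2[{j}] must be > 0, got {tau2}")
    pj = ctx.group_sizes[j]
    shape = ctx.hyper.a_gamma + 0.5 * (pj + 1)
    rate = ctx.hyper.b_gamma + 0.5 * tau2
    return float(ctx.rng.gamma(shape, 1.0 / rate))


def sample_tau_alpha_inv2(l: int, ctx: ConditionalContext) -> float:
    """tau_al^-2 | . ~ IG(mean = sqrt(lambda_l^2 sigma^2 / alpha_l^2),
    shape = lambda_l^2)."""
    sigma2 = ctx.params.sigma2
    lam2 = ctx.params.lambda2[l]
    if not sigma2 > 0:
        raise ValueError("sigma2 must be > 0")
    abs_alpha = abs(float(ctx.params.alpha[l]))
    if abs_alpha < MAGNITUDE_FLOOR:
        logger.warning(
            "alpha[%d] magnitude %.3e below floor; clamping for tau update",
            l,
            abs_alpha,
        )
        abs_alpha = MAGNITUDE_FLOOR
    mean = np.sqrt(lam2 * sigma2) / abs_alpha
    return float(sample_inverse_gaussian(ctx.rng, mean, lam2))


def sample_tau_group_inv2(j: int, ctx: ConditionalContext) -> float:
    """tau_Gj^-2 | . ~ IG(mean = sqrt(gamma_j^2 sigma^2 / ||beta_Gj||_K^2),
    shape = gamma_j^2), with ||beta_Gj||_K^2 = p_j beta_Gj' beta_Gj."""
    sigma2 = ctx.params.sigma2
    gam2 = ctx.params.gamma2[j]
    if not (sigma2 > 0 and gam2 > 0):
        raise ValueError("sigma2 and gamma2 must be > 0")
    beta_j = ctx.params.beta[ctx.group_slices[j]]
    knorm = np.sqrt(ctx.group_sizes[j] * float(beta_j @ beta_j))
    if knorm < MAGNITUDE_FLOOR:
        logger.warning(
            "||beta_G%d||_K %.3e below floor; clamping for tau update", j, knorm
        )
        knorm = MAGNITUDE_FLOOR
    mean = np.sqrt(gam2 * sigma2) / knorm
    return float(sample_inverse_gaussian(ctx.rng, mean, gam2))


def _mvn_draw(
    rng: np.random.Generator,
    precision: np.ndarray,
    xty: np.ndarray,
    sigma2: float,
) -> np.ndarray:
    """Draw from N(A^-1 xty, sigma2 A^-1) via Cholesky of A = precision."""
    chol = linalg.cho_factor(precision, lower=True)
    mean = linalg.cho_solve(chol, xty)
    # solve L' w = z gives w ~ N(0, A^-1)
    z = rng.standard_normal(xty.shape[0])
    w = linalg.solve_triangular(chol[0], z, lower=True, trans="T")
    return mean + np.sqrt(sigma2) * w


def sample_alpha(ctx: ConditionalContext) -> np.ndarray:
    """alpha | . ~ N(A^-1 X_a' Y_a, sigma^2 A^-1) with
    A = X_a'X_a + Sigma_alpha^-1 and Y_a = y - X_beta beta (partial
    residual removing the grouped block)."""
    L = ctx.params.alpha.shape[0]
    if L == 0:
        return np.empty(0)
    if np.any(ctx.params.tau_alpha2 <= 0):
        raise ValueError("tau_alpha2 must be strictly positive")
    y_partial = ctx.y - ctx.X_beta @ ctx.params.beta
    A = ctx.X_alpha.T @ ctx.X_alpha + np.diag(1.0 / ctx.params.tau_alpha2)
    return _mvn_draw(ctx.rng, A, ctx.X_alpha.T @ y_partial, ctx.params.sigma2)


def sample_beta_group(j: int, ctx: ConditionalContext) -> np.ndarray:
    """beta_Gj | . ~ N(B^-1 X_Gj' Y_Gj, sigma^2 B^-1) with
    B = X_Gj'X_Gj + tau_Gj^-2 K_j and Y_Gj the partial residual excluding
    group j."""
    tau2 = ctx.params.tau_group2[j]
    if not tau2 > 0:
        raise ValueError(f"tau_group2[{j}] must be > 0, got {tau2}")
    sl = ctx.group_slices[j]
    pj = ctx.group_sizes[j]
    Xj = ctx.X_beta[:, sl]
    # y minus alpha block and every other group's contribution
    fitted_other = ctx.X_beta @ ctx.params.beta - Xj @ ctx.params.beta[sl]
    y_partial = ctx.y - ctx.X_alpha @ ctx.params.alpha - fitted_other
    B = Xj.T @ Xj + (pj / tau2) * np.eye(pj)
    return _mvn_draw(ctx.rng, B, Xj.T @ y_partial, ctx.params.sigma2)


def sample_sigma_inv2(ctx: ConditionalContext) -> float:
    """sigma^-2 | . ~ Gamma(a + (n_s + L + p)/2, rate = b + (SS_resid +
    alpha' Sigma_a^-1 alpha + sum_j tau_Gj^-2 ||beta_Gj||_K^2) / 2).

    n_s is the count of observations currently in the state; the quadratic
    prior terms enter because alpha and beta are scaled by sigma in the
    hierarchy.
    """
    p = ctx.params.beta.shape[0]
    L = ctx.params.alpha.shape[0]
    resid = ctx.y - ctx.X_alpha @ ctx.params.alpha - ctx.X_beta @ ctx.params.beta
    ss = float(resid @ resid)
    ss += float(ctx.params.alpha**2 @ (1.0 / ctx.params.tau_alpha2))
    for j, sl in enumerate(ctx.group_slices):
        beta_j = ctx.params.beta[sl]
        ss += ctx.group_sizes[j] / ctx.params.tau_group2[j] * float(beta_j @ beta_j)
    shape = ctx.hyper.a + 0.5 * (ctx.n_obs + L + p)
    rate = ctx.hyper.b + 0.5 * ss
    return float(ctx.rng.gamma(shape, 1.0 / rate))


def sweep_state(ctx: ConditionalContext) -> StateParameters:
    """One Gauss–Seidel sweep over every block of one state, in the fixed
    order: alpha, beta groups, sigma^-2, tau^-2 scales, penalty parameters.

    Mutates and returns ``ctx.params``.
    """
    params = ctx.params
    if ctx.params.alpha.shape[0]:
        params.alpha = sample_alpha(ctx)
    for j in range(len(ctx.group_sizes)):
        params.beta[ctx.group_slices[j]] = sample_beta_group(j, ctx)
    params.sigma2 = 1.0 / sample_sigma_inv2(ctx)
    for l in range(params.alpha.shape[0]):
        params.tau_alpha2[l] = 1.0 / sample_tau_alpha_inv2(l, ctx)
    for j in range(len(ctx.group_sizes)):
        params.tau_group2[j] = 1.0 / sample_tau_group_inv2(j, ctx)
    for l in range(params.alpha.shape[0]):
        params.lambda2[l] = sample_lambda2(l, ctx)
    for j in range(len(ctx.group_sizes)):
        params.gamma2[j] = sample_gamma2(j, ctx)
    return params


def sample_prior_params(
    structure_L: int,
    group_sizes: tuple[int, ...],
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> StateParameters:
    """Draw one StateParameters block from the full hierarchical prior.

    Used for dispersed chain starts and for empty-state refreshes.
    """
    J = len(group_sizes)
    lambda2 = rng.gamma(hyper.a_lambda, 1.0 / hyper.b_lambda, size=structure_L)
    gamma2 = rng.gamma(hyper.a_gamma, 1.0 / hyper.b_gamma, size=J)
    sigma2 = 1.0 / rng.gamma(hyper.a, 1.0 / hyper.b)
    tau_alpha2 = rng.exponential(2.0 / lambda2) if structure_L else np.empty(0)
    tau_group2 = np.array(
        [rng.gamma(0.5 * (pj + 1), 2.0 / gamma2[j]) for j, pj in enumerate(group_sizes)]
    )
    alpha = rng.standard_normal(structure_L) * np.sqrt(sigma2 * tau_alpha2)
    beta = np.concatenate(
        [
            rng.standard_normal(pj) * np.sqrt(sigma2 * tau_group2[j] / pj)
            for j, pj in enumerate(group_sizes)
        ]
    )
    return StateParameters(
        alpha=alpha,
        beta=beta,
        sigma2=float(sigma2),
        tau_alpha2=np.maximum(tau_alpha2, 1e-300),
        lambda2=lambda2,
        tau_group2=tau_group2,
        gamma2=gamma2,
    )
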