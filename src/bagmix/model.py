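"""Domain types for the hidden-state mixed linear regression model.

The model: for subject i = 1..N at occasion t = 1..T, conditional on the
latent state S_it = s,

    y_it = x_it theta_s + u_i + eps_it,      eps_it ~ N(0, sigma_s^2),

where theta_s = (alpha_s, beta_s) stacks L ungrouped coefficients and p
grouped coefficients partitioned into J groups G_1..G_J, and u_i is a
subject-level random intercept.  Sampling runs on the *collapsed* model in
which Sigma + Z D Z' is approximated by sigma*^2 I, i.e. the random
intercept is absorbed into a single state-specific error variance and is
never sampled; u_i exists only in the synthetic-data generator.

States are i.i.d. categorical, P(S_it = s) = q_s.  Observations are stored
flattened row-major by subject then occasion (0-based internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DimensionError(ValueError):
    """Raised when a data block has inconsistent dimensions."""


@dataclass(frozen=True)
class GroupStructure:
    """Partition of the coefficient vector into ungrouped and grouped blocks.

    Parameters
    ----------
    L : int
        Number of ungrouped covariates (the alpha block).
    group_sizes : tuple of int
        p_j for j = 1..J; the beta block has p = sum(p_j) columns, with
        group j occupying a contiguous slice of it.
    """

    L: int
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_sizes", tuple(int(s) for s in self.group_sizes))
        if self.L < 0:
            raise ValueError(f"L must be >= 0, got {self.L}")
        if len(self.group_sizes) < 1:
            raise ValueError("at least one group is required")
        if any(s < 1 for s in self.group_sizes):
            raise ValueError(f"every group size must be >= 1, got {self.group_sizes}")

    @property
    def J(self) -> int:
        return len(self.group_sizes)

    @property
    def p(self) -> int:
        return int(sum(self.group_sizes))

    @property
    def n_coef(self) -> int:
        return self.L + self.p

    @property
    def group_slices(self) -> list[slice]:
        """Slice of each group into the beta block (0-based, contiguous)."""
        edges = np.concatenate([[0], np.cumsum(self.group_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    @property
    def group_index_sets(self) -> list[list[int]]:
        return [list(range(s.start, s.stop)) for s in self.group_slices]

    def penalty_matrix(self, j: int) -> np.ndarray:
        """K_j = p_j * I_{p_j}, the group-j norm metric."""
        pj = self.group_sizes[j]
        return pj * np.eye(pj)


@dataclass(frozen=True)
class Hyperparameters:
    """Hyperparameters of the hierarchical prior.

    sigma^2 ~ InvGamma(a, b); lambda_l^2 ~ Gamma(a_lambda, rate=b_lambda);
    gamma_j^2 ~ Gamma(a_gamma, rate=b_gamma).  All Gammas are rate
    parameterized.
    """

    a: float = 1.0
    b: float = 0.1
    a_lambda: float = 1.0
    b_lambda: float = 0.1
    a_gamma: float = 1.0
    b_gamma: float = 0.01

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_lambda", "b_lambda", "a_gamma", "b_gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"hyperparameter {name} must be finite and > 0, got {v}")

    @classmethod
    def default(cls) -> "Hyperparameters":
        """Weakly informative reference prior used throughout the simulations."""
        return cls(a=1.0, b=0.1, a_lambda=1.0, b_lambda=0.1, a_gamma=1.0, b_gamma=0.01)

    @classmethod
    def alternative(cls) -> "Hyperparameters":
        """More informative prior used for the sensitivity analysis."""
        return cls(a=6.0, b=4.0, a_lambda=2.0, b_lambda=0.01, a_gamma=3.0, b_gamma=0.05)


@dataclass
class Dataset:
    """Longitudinal design data, flattened to N*T rows (subject-major).

    ``X_alpha`` holds the ungrouped covariates, ``X_beta`` the grouped block
    ordered per ``structure``.  ``true_states`` (1-based labels) is optional
    simulation truth.
    """

    y: np.ndarray
    X_alpha: np.ndarray
    X_beta: np.ndarray
    structure: GroupStructure
    N: int
    T: int
    true_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X_alpha = np.atleast_2d(np.asarray(self.X_alpha, dtype=float))
        self.X_beta = np.atleast_2d(np.asarray(self.X_beta, dtype=float))
        n_rows = self.N * self.T
        if self.y.shape[0] != n_rows:
            raise DimensionError(
                f"y has {self.y.shape[0]} rows, expected N*T = {n_rows}"
            )
        if self.X_alpha.shape != (n_rows, self.structure.L):
            raise DimensionError(
                f"X_alpha block has shape {self.X_alpha.shape}, "
                f"expected ({n_rows}, {self.structure.L})"
            )
        if self.X_beta.shape != (n_rows, self.structure.p):
            raise DimensionError(
                f"X_beta block has shape {self.X_beta.shape}, "
                f"expected ({n_rows}, {self.structure.p})"
            )
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states, dtype=int).ravel()
            if self.true_states.shape[0] != n_rows:
                raise DimensionError("true_states length does not match N*T")
            if self.true_states.min() < 1:
                raise ValueError("true_states labels must be >= 1")

    @property
    def n_obs(self) -> int:
        return self.N * self.T

    @property
    def X(self) -> np.ndarray:
        """Full design [X_alpha | X_beta] in theta order."""
        return np.hstack([self.X_alpha, self.X_beta])

    @property
    def subject_index(self) -> np.ndarray:
        """0-based subject index of each row (the implicit z_it indicator)."""
        return np.repeat(np.arange(self.N), self.T)


@dataclass
class StateParameters:
    """Parameter block zeta_s of one hidden state.

    alpha, beta are the regression coefficients; sigma2 the collapsed error
    variance; tau_alpha2 / tau_group2 the latent Laplace scale mixtures;
    lambda2 / gamma2 the (squared) adaptive penalty parameters.
    """

    alpha: np.ndarray
    beta: np.ndarray
    sigma2: float
    tau_alpha2: np.ndarray
    lambda2: np.ndarray
    tau_group2: np.ndarray
    gamma2: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        for name in ("tau_alpha2", "lambda2", "tau_group2", "gamma2"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            setattr(self, name, arr)
            if arr.size and arr.min() <= 0:
                raise ValueError(f"{name} entries must be strictly positive")
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be > 0, got {self.sigma2}")

    @property
    def theta(self) -> np.ndarray:
        return pack_theta(self.alpha, self.beta)

    @classmethod
    def initial(cls, structure: GroupStructure) -> "StateParameters":
        """Zero coefficients, unit scales."""
        return cls(
            alpha=np.zeros(structure.L),
            beta=np.zeros(structure.p),
            sigma2=1.0,
            tau_alpha2=np.ones(structure.L),
            lambda2=np.ones(structure.L),
            tau_group2=np.ones(structure.J),
            gamma2=np.ones(structure.J),
        )


@dataclass
class MixtureState:
    """Full sampler state: S per-state parameter blocks, mixing weights,
    and the current 1-based state assignment of every observation."""

    S: int
    params: list[StateParameters]
    q: np.ndarray
    assignments: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.assignments = np.asarray(self.assignments, dtype=int).ravel()
        if len(self.params) != self.S:
            raise ValueError("need one StateParameters per state")
        if self.q.shape[0] != self.S:
            raise ValueError("q must have one weight per state")
        if not np.isclose(self.q.sum(), 1.0):
            raise ValueError(f"q must sum to 1, got {self.q.sum()}")
        if np.any((self.q < -1e-12) | (self.q > 1 + 1e-12)):
            raise ValueError("q entries must lie in [0, 1]")
        if self.assignments.size and (
            self.assignments.min() < 1 or self.assignments.max() > self.S
        ):
            raise ValueError("assignments must lie in {1..S}")


def pack_theta(alpha: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """theta = (alpha_1..alpha_L, beta_G1..beta_GJ)."""
    return np.concatenate([np.ravel(alpha), np.ravel(beta)])


def unpack_theta(
    theta: np.ndarray, structure: GroupStructure
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_theta` under a given group structure."""
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != structure.n_coef:
        raise DimensionError(
            f"theta has length {theta.shape[0]}, expected {structure.n_coef}"
        )
    return theta[: structure.L].copy(), theta[structure.L :].copy()


def collapsed_residual(
    dataset: Dataset,
    state_params: StateParameters,
    assignments: np.ndarray,
    state_id: int,
) -> np.ndarray:
    """Residual y - X theta_s over the rows currently assigned to state_id.

    Rows are returned flattened in (subject, occasion) order.  ``state_id``
    is 1-based, matching assignment labels.
    """
    structure = dataset.structure
    if state_params.alpha.shape[0] != structure.L:
        raise DimensionError(
            f"alpha block has length {state_params.alpha.shape[0]}, expected L={structure.L}"
        )
    if state_params.beta.shape[0] != structure.p:
        raise DimensionError(
            f"beta block has length {state_params.beta.shape[0]}, expected p={structure.p}"
        )
    assignments = np.asarray(assignments, dtype=int).ravel()
    if assignments.shape[0] != dataset.n_obs:
        raise DimensionError("assignments length does not match N*T")
    mask = assignments == state_id
    fitted = dataset.X_alpha[mask] @ state_params.alpha + dataset.X_beta[mask] @ state_params.beta
    return dataset.y[mask] - fitted


_LOG_2PI = float(np.log(2.0 * np.pi))


def log_likelihood_obs(
    y_it: float, x_it: np.ndarray, state_params: StateParameters
) -> float:
    """log N(y_it; x_it theta_s, sigma_s^2) under the collapsed model."""
    s2 = state_params.sigma2
    if not s2 > 0:
        raise ValueError(f"sigma2 must be > 0, got {s2}")
    resid = float(y_it) - float(np.dot(np.ravel(x_it), state_params.theta))
    return -0.5 * (_LOG_2PI + np.log(s2) + resid * resid / s2)
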