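"""Synthetic longitudinal data with hidden-state mixture structure.

The default :func:`two_state_design` reproduces the simulation conditions
used throughout the package's validation study: N subjects observed at
T = 3 occasions, two equally weighted hidden states, L = 2 ungrouped
covariates and three groups of three correlated covariates each
(AR-type within-group correlation rho_j^|i-k| with rho = 0.7, 0.6, 0.4),
a standard-normal subject random intercept and standard-normal noise.
State-specific truths include entire all-zero groups as well as a group
with a single zero component, so both the correct and the strict
(all-components) elimination behavior of the group selection rule are
exercised.

State labels are drawn i.i.d. per observation (i, t); a per-subject
option is available for case-study-like structure where a subject stays
in one state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .model import Dataset, GroupStructure, pack_theta


@dataclass
class SimulationDesign:
    """Everything needed to simulate one dataset.

    ``alpha[s]`` and ``beta_groups[s][j]`` give state s's true ungrouped
    coefficients and group-j coefficient vector.  ``ar_corr[j]`` is the
    base rho_j of the within-group AR correlation rho_j^|i-k|.
    """

    N: int
    T: int
    S: int
    q_true: np.ndarray
    alpha: list[np.ndarray]
    beta_groups: list[list[np.ndarray]]
    ar_corr: np.ndarray
    sigma_u2: float = 1.0
    sigma_eps2: float = 1.0
    state_per_subject: bool = False
    intercept: bool = False

    def __post_init__(self) -> None:
        self.q_true = np.asarray(self.q_true, dtype=float).ravel()
        self.ar_corr = np.asarray(self.ar_corr, dtype=float).ravel()
        if not np.isclose(self.q_true.sum(), 1.0):
            raise ValueError("q_true must sum to 1")
        if np.any(np.abs(self.ar_corr) >= 1):
            raise ValueError("AR correlations must lie in (-1, 1)")
        if self.sigma_u2 < 0 or self.sigma_eps2 < 0:
            raise ValueError("variances must be >= 0")
        self.alpha = [np.asarray(a, dtype=float).ravel() for a in self.alpha]
        self.beta_groups = [
            [np.asarray(b, dtype=float).ravel() for b in groups]
            for groups in self.beta_groups
        ]

    @property
    def structure(self) -> GroupStructure:
        L = self.alpha[0].shape[0] + (1 if self.intercept else 0)
        sizes = tuple(b.shape[0] for b in self.beta_groups[0])
        return GroupStructure(L=L, group_sizes=sizes)

    def theta(self, s: int) -> np.ndarray:
        """True stacked coefficient vector of state s (0-based)."""
        alpha = self.alpha[s]
        if self.intercept:
            alpha = np.concatenate([[0.0], alpha])
        return pack_theta(alpha, np.concatenate(self.beta_groups[s]))

    def zero_groups(self) -> list[list[int]]:
        """Per state, the indices of groups whose truth is all-zero."""
        return [
            [j for j, b in enumerate(groups) if np.all(b == 0)]
            for groups in self.beta_groups
        ]


def two_state_design(n: int = 100, seed: int | None = None) -> SimulationDesign:
    """The reference two-state design at sample size ``n`` (subjects).

    State 1: alpha = (-1.7, 1.3); groups (2.0, -0.4, 1.3), (0.6, 0, -1.1),
    (0, 0, 0).  State 2: alpha = (0.3, -1.2); groups (0,0,0), (0,0,0),
    (-1.5, 2.2, 0.5).  T = 3, equal mixing weights, unit random-intercept
    and error variances, group correlations 0.7 / 0.6 / 0.4.

    ``n`` = 100 or 300 match the validation study; other values are
    allowed for exploration.
    """
    return SimulationDesign(
        N=int(n),
        T=3,
        S=2,
        q_true=np.array([0.5, 0.5]),
        alpha=[np.array([-1.7, 1.3]), np.array([0.3, -1.2])],
        beta_groups=[
            [np.array([2.0, -0.4, 1.3]), np.array([0.6, 0.0, -1.1]), np.zeros(3)],
            [np.zeros(3), np.zeros(3), np.array([-1.5, 2.2, 0.5])],
        ],
        ar_corr=np.array([0.7, 0.6, 0.4]),
        sigma_u2=1.0,
        sigma_eps2=1.0,
    )


def _ar_cholesky(rho: float, p: int) -> np.ndarray:
    cov = rho ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    return linalg.cholesky(cov, lower=True)


def simulate(design: SimulationDesign, rng: np.random.Generator | int) -> Dataset:
    """Draw one dataset from the design.

    Per row (i, t): S_it ~ Categorical(q_true); ungrouped covariates
    ~ N(0, I); group-j covariates ~ N(0, Sigma_j) with
    (Sigma_j)_{ik} = rho_j^|i-k|; and
    y_it = x_it theta_{S_it} + u_i + eps_it with u_i ~ N(0, sigma_u2)
    drawn once per subject, eps_it ~ N(0, sigma_eps2).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    structure = design.structure
    n_rows = design.N * design.T

    if design.state_per_subject:
        subject_states = 1 + _categorical(rng, design.q_true, design.N)
        states = np.repeat(subject_states, design.T)
    else:
        states = 1 + _categorical(rng, design.q_true, n_rows)

    L_raw = design.alpha[0].shape[0]
    X_alpha = rng.standard_normal((n_rows, L_raw))
    if design.intercept:
        X_alpha = np.hstack([np.ones((n_rows, 1)), X_alpha])
    blocks = []
    for j, sl in enumerate(structure.group_slices):
        p_j = sl.stop - sl.start
        z = rng.standard_normal((n_rows, p_j))
        blocks.append(z @ _ar_cholesky(float(design.ar_corr[j]), p_j).T)
    X_beta = np.hstack(blocks)

    thetas = np.stack([design.theta(s) for s in range(design.S)])
    X = np.hstack([X_alpha, X_beta])
    mean = np.einsum("ij,ij->i", X, thetas[states - 1])
    u = rng.standard_normal(design.N) * np.sqrt(design.sigma_u2)
    eps = rng.standard_normal(n_rows) * np.sqrt(design.sigma_eps2)
    y = mean + np.repeat(u, design.T) + eps

    return Dataset(
        y=y,
        X_alpha=X_alpha,
        X_beta=X_beta,
        structure=structure,
        N=design.N,
        T=design.T,
        true_states=states,
    )


def _categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(probs)
    return (rng.uniform(size=n)[:, None] > cum[None, :]).sum(axis=1)
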