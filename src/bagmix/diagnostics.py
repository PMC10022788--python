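"""Convergence monitoring and the replication study harness.

EPSR (estimated potential scale reduction, the Gelman–Rubin statistic) is
computed from parallel chains started at dispersed initial values; values
below 1.2 for every monitored parameter are taken as convergence
evidence.  The replication harness runs simulate → fit → relabel →
select cycles, permutation-matches each fit's states to the simulation
truth, and aggregates bias/RMSE of the posterior means, the
correct/incorrect-zero counts, per-group selection frequencies, and
state-classification accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gibbs import ChainConfig, ChainResult, relabel_states, run_chain
from .model import Hyperparameters
from .selection import SelectionResult, count_selection_outcomes, select
from .synthetic import SimulationDesign, simulate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameter naming / extraction

def param_names(S: int, L: int, group_sizes: tuple[int, ...], include_scales: bool = False) -> list[str]:
    """Monitored parameter names, 1-based, e.g. ``state1.alpha2``,
    ``state1.betaG2.3``, ``state2.sigma2``."""
    names = []
    for s in range(1, S + 1):
        for l in range(1, L + 1):
            names.append(f"state{s}.alpha{l}")
        for j, pj in enumerate(group_sizes, start=1):
            for c in range(1, pj + 1):
                names.append(f"state{s}.betaG{j}.{c}")
        names.append(f"state{s}.sigma2")
        if include_scales:
            for l in range(1, L + 1):
                names.append(f"state{s}.lambda2{l}")
            for j in range(1, len(group_sizes) + 1):
                names.append(f"state{s}.gamma2{j}")
    return names


def param_draws(chain: ChainResult, name: str) -> np.ndarray:
    """Draw vector (length n_iter) for one named parameter."""
    state_part, _, rest = name.partition(".")
    s = int(state_part.removeprefix("state")) - 1
    if rest.startswith("alpha"):
        return chain.alpha[:, s, int(rest.removeprefix("alpha")) - 1]
    if rest.startswith("betaG"):
        j_part, c_part = rest.removeprefix("betaG").split(".")
        j, c = int(j_part) - 1, int(c_part) - 1
        # groups are contiguous; recover the offset from stored slices
        sizes = _group_sizes_from_beta(chain)
        offset = int(np.sum(sizes[:j]))
        return chain.beta[:, s, offset + c]
    if rest == "sigma2":
        return chain.sigma2[:, s]
    if rest.startswith("lambda2"):
        return chain.lambda2[:, s, int(rest.removeprefix("lambda2")) - 1]
    if rest.startswith("gamma2"):
        return chain.gamma2[:, s, int(rest.removeprefix("gamma2")) - 1]
    if rest == "q":
        return chain.q[:, s]
    raise KeyError(f"unknown parameter name {name!r}")


def _group_sizes_from_beta(chain: ChainResult) -> np.ndarray:
    J = chain.gamma2.shape[2]
    p = chain.beta.shape[2]
    if p % J == 0:
        return np.full(J, p // J)
    raise KeyError(
        "cannot infer unequal group sizes from a chain; use explicit indexing"
    )


# ---------------------------------------------------------------------------
# EPSR

def epsr(
    chains: list[ChainResult] | np.ndarray,
    param_name: str | None = None,
    window: tuple[int, int] | None = None,
) -> float:
    """Gelman–Rubin potential scale reduction over parallel chains.

    ``chains`` is either a list of ChainResult (then ``param_name`` names
    the monitored scalar) or an (m, n) array of draws.  ``window``
    restricts to iterations [start, stop); by default the second half of
    the available draws is used.
    """
    if isinstance(chains, np.ndarray):
        draws = np.atleast_2d(chains)
    else:
        if len(chains) < 2:
            raise ValueError("EPSR needs at least 2 chains")
        draws = np.stack([param_draws(c, param_name) for c in chains])
    if window is None:
        stop = draws.shape[1]
        window = (stop // 2, stop)
    start, stop = window
    draws = draws[:, start:stop]
    m, n = draws.shape
    if n < 50:
        raise ValueError(f"need >= 50 draws in the window, got {n}")
    chain_means = draws.mean(axis=1)
    W = float(draws.var(axis=1, ddof=1).mean())
    if W == 0:
        raise ValueError("zero within-chain variance: degenerate draws")
    B_over_n = float(chain_means.var(ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def epsr_all(
    chains: list[ChainResult],
    group_sizes: tuple[int, ...],
    window: tuple[int, int] | None = None,
    include_scales: bool = False,
) -> dict[str, float]:
    """EPSR of every monitored coefficient and variance parameter."""
    S, L = chains[0].S, chains[0].alpha.shape[2]
    return {
        name: epsr(chains, name, window)
        for name in param_names(S, L, group_sizes, include_scales)
    }


# ---------------------------------------------------------------------------
# bias / RMSE

def bias_rmse(
    estimates_over_reps: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter bias and RMSE across replications (axis 0)."""
    est = np.asarray(estimates_over_reps, dtype=float)
    if est.shape[0] < 2:
        raise ValueError("need >= 2 replications")
    err = est - np.asarray(truth, dtype=float)[None, ...]
    return err.mean(axis=0), np.sqrt((err**2).mean(axis=0))


# ---------------------------------------------------------------------------
# replication harness

@dataclass
class ReplicationReport:
    """Aggregated results of R simulate→fit→select replications."""

    design: SimulationDesign
    n_replications: int
    alpha_bias: np.ndarray
    alpha_rmse: np.ndarray
    beta_bias: np.ndarray
    beta_rmse: np.ndarray
    corr: np.ndarray
    incorr: np.ndarray
    group_counts: np.ndarray
    accuracy: np.ndarray
    alpha_means: np.ndarray
    beta_means: np.ndarray
    alpha_kept_counts: np.ndarray | None = None
    failures: list[str] = field(default_factory=list)


def permute_chain_states(chain: ChainResult, perm: list[int]) -> ChainResult:
    """Globally relabel a chain so that new state i <- old state perm[i]."""
    idx = list(perm)
    for arr in (
        chain.alpha,
        chain.beta,
        chain.sigma2,
        chain.lambda2,
        chain.gamma2,
        chain.tau_alpha2,
        chain.tau_group2,
        chain.q,
    ):
        arr[:] = arr[:, idx]
    inv = np.empty(len(idx), dtype=chain.assignments.dtype)
    for new, old in enumerate(idx):
        inv[old] = new + 1
    chain.assignments[:] = inv[chain.assignments - 1]
    return chain


def match_states_to_truth(
    chain: ChainResult, true_states: np.ndarray
) -> ChainResult:
    """Permute chain labels to best agree with the simulation truth.

    Builds the confusion matrix between per-observation posterior-mode
    states and the true labels and solves the assignment problem
    maximizing agreement (Hungarian algorithm).
    """
    S = chain.S
    modal = chain.modal_states()
    confusion = np.zeros((S, S))
    for est in range(S):
        for tru in range(S):
            confusion[est, tru] = np.sum((modal == est + 1) & (true_states == tru + 1))
    est_idx, true_idx = linear_sum_assignment(-confusion)
    perm = [0] * S
    for e, t in zip(est_idx, true_idx):
        perm[t] = e
    return permute_chain_states(chain, perm)


def replicate(
    design: SimulationDesign,
    hyperparams: Hyperparameters,
    chain_config: ChainConfig,
    R: int,
    level: float = 0.95,
) -> ReplicationReport:
    """Run R independent simulate→fit→relabel→match→select cycles.

    Seeds for each replication's data and chain are spawned from
    ``chain_config.seed``; per-replication failures are logged and
    excluded, fatal only if every replication fails.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    structure = design.structure
    truth_alpha = np.stack(
        [design.theta(s)[: structure.L] for s in range(design.S)]
    )
    truth_beta = np.stack(
        [design.theta(s)[structure.L :] for s in range(design.S)]
    )

    alpha_means, beta_means, accuracy = [], [], []
    selections: list[SelectionResult] = []
    failures: list[str] = []
    for r in range(R):
        try:
            data_rng = np.random.default_rng(
                np.random.SeedSequence([chain_config.seed, r, 0])
            )
            chain_rng = np.random.default_rng(
                np.random.SeedSequence([chain_config.seed, r, 1])
            )
            dataset = simulate(design, data_rng)
            chain = run_chain(dataset, design.S, hyperparams, chain_config, rng=chain_rng)
            if design.S >= 2:
                relabel_states([chain])
                chain = match_states_to_truth(chain, dataset.true_states)
            sel = select(chain, structure.group_slices, level=level)
            alpha_means.append(sel.alpha_mean)
            beta_means.append(sel.beta_mean)
            accuracy.append(
                float(np.mean(chain.modal_states() == dataset.true_states))
            )
            selections.append(sel)
        except Exception as exc:  # noqa: BLE001 - harness isolates failures
            logger.exception("replication %d failed", r)
            failures.append(f"replication {r}: {exc}")
    if not selections:
        raise RuntimeError(f"all {R} replications failed: {failures}")

    alpha_arr = np.stack(alpha_means)
    beta_arr = np.stack(beta_means)
    a_bias, a_rmse = bias_rmse(alpha_arr, truth_alpha)
    b_bias, b_rmse = bias_rmse(beta_arr, truth_beta)
    outcomes = count_selection_outcomes(selections, design.zero_groups())
    kept_counts = np.zeros((design.S, structure.L), dtype=int)
    for sel in selections:
        for s in range(design.S):
            for l in sel.kept_alpha[s]:
                kept_counts[s, l] += 1
    return ReplicationReport(
        design=design,
        n_replications=len(selections),
        alpha_bias=a_bias,
        alpha_rmse=a_rmse,
        beta_bias=b_bias,
        beta_rmse=b_rmse,
        corr=outcomes["corr"],
        incorr=outcomes["incorr"],
        group_counts=outcomes["group_counts"],
        accuracy=np.asarray(accuracy),
        alpha_means=alpha_arr,
        beta_means=beta_arr,
        alpha_kept_counts=kept_counts,
        failures=failures,
    )
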