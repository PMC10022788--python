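"""Credible-interval variable selection on post-burn-in draws.

The rule, applied per hidden state: an ungrouped coefficient alpha_l is
kept iff its 95% equal-tailed posterior interval excludes zero; a grouped
block beta_Gj is kept iff EVERY component's interval excludes zero — if
any single component's interval covers zero the whole group is dropped.
The strict all-components group rule is deliberate: with a group like
(0.6, 0, -1.1) the zero middle component eliminates the entire group even
though two components are clearly nonzero.

Point estimates are posterior means.  Intervals are equal-tailed quantile
intervals by default; highest-posterior-density intervals are available
via ``interval="hpd"`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gibbs import ChainResult

MIN_DRAWS = 100


@dataclass
class SelectionResult:
    """Per-state selection decisions and posterior summaries.

    ``kept_alpha[s]`` / ``kept_groups[s]`` are 0-based index lists for
    state s (0-based).  ``alpha_intervals`` etc. have shapes
    (S, L, 2), (S, p, 2); point estimates (S, L) and (S, p).
    """

    kept_alpha: list[list[int]]
    kept_groups: list[list[int]]
    alpha_intervals: np.ndarray
    beta_intervals: np.ndarray
    alpha_mean: np.ndarray
    beta_mean: np.ndarray
    level: float
    group_slices: list[slice] = field(default_factory=list)


def credible_interval(
    draws: np.ndarray, level: float = 0.95, interval: str = "eti"
) -> tuple[float, float]:
    """Equal-tailed (or HPD) posterior interval from a draw vector."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < MIN_DRAWS:
        raise ValueError(f"need >= {MIN_DRAWS} draws, got {draws.size}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    if interval == "eti":
        lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)
    if interval == "hpd":
        x = np.sort(draws)
        m = int(np.ceil(level * x.size))
        widths = x[m - 1 :] - x[: x.size - m + 1]
        i = int(np.argmin(widths))
        return float(x[i]), float(x[i + m - 1])
    raise ValueError(f"unknown interval type {interval!r}")


def _interval_matrix(
    draws: np.ndarray, level: float, interval: str
) -> np.ndarray:
    """(d, 2) intervals for an (n_draws, d) draw matrix."""
    if draws.shape[0] < MIN_DRAWS:
        raise ValueError(f"need >= {MIN_DRAWS} draws, got {draws.shape[0]}")
    if interval == "eti":
        qs = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
        return qs.T
    return np.array(
        [credible_interval(draws[:, i], level, interval) for i in range(draws.shape[1])]
    )


def select_alpha(
    chain: ChainResult, level: float = 0.95, interval: str = "eti"
) -> list[list[int]]:
    """Kept alpha indices per state: interval excludes zero."""
    post = chain.post_burnin()
    kept = []
    for s in range(chain.S):
        ivals = _interval_matrix(post.alpha[:, s, :], level, interval)
        kept.append([l for l in range(ivals.shape[0]) if ivals[l, 0] > 0 or ivals[l, 1] < 0])
    return kept


def select_groups(
    chain: ChainResult,
    group_slices: list[slice],
    level: float = 0.95,
    interval: str = "eti",
) -> list[list[int]]:
    """Kept group indices per state: every component interval excludes zero."""
    post = chain.post_burnin()
    kept = []
    for s in range(chain.S):
        ivals = _interval_matrix(post.beta[:, s, :], level, interval)
        excludes = (ivals[:, 0] > 0) | (ivals[:, 1] < 0)
        kept.append([j for j, sl in enumerate(group_slices) if excludes[sl].all()])
    return kept


def select(
    chain: ChainResult,
    group_slices: list[slice],
    level: float = 0.95,
    interval: str = "eti",
) -> SelectionResult:
    """Full selection pass over a (relabeled) chain."""
    post = chain.post_burnin()
    S = chain.S
    a_ivals = np.stack(
        [_interval_matrix(post.alpha[:, s, :], level, interval) for s in range(S)]
    )
    b_ivals = np.stack(
        [_interval_matrix(post.beta[:, s, :], level, interval) for s in range(S)]
    )
    return SelectionResult(
        kept_alpha=select_alpha(chain, level, interval),
        kept_groups=select_groups(chain, group_slices, level, interval),
        alpha_intervals=a_ivals,
        beta_intervals=b_ivals,
        alpha_mean=post.alpha.mean(axis=0),
        beta_mean=post.beta.mean(axis=0),
        level=level,
        group_slices=group_slices,
    )


def count_selection_outcomes(
    replication_results: list[SelectionResult],
    zero_groups: list[list[int]],
) -> dict:
    """Aggregate group-selection decisions across replications.

    ``zero_groups[s]`` lists the group indices whose true coefficient
    vector is all-zero in state s.  Returns per state the average number
    of truly-zero groups eliminated (``corr``), the average number of
    nonzero groups eliminated (``incorr``), and per-group selection
    counts across replications.
    """
    if not replication_results:
        raise ValueError("no replication results")
    S = len(replication_results[0].kept_groups)
    J = len(replication_results[0].group_slices)
    counts = np.zeros((S, J), dtype=int)
    corr = np.zeros(S)
    incorr = np.zeros(S)
    for res in replication_results:
        for s in range(S):
            kept = set(res.kept_groups[s])
            for j in kept:
                counts[s, j] += 1
            dropped = set(range(J)) - kept
            truly_zero = set(zero_groups[s])
            corr[s] += len(dropped & truly_zero)
            incorr[s] += len(dropped - truly_zero)
    R = len(replication_results)
    return {
        "n_replications": R,
        "corr": corr / R,
        "incorr": incorr / R,
        "group_counts": counts,
    }
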