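import numpy as np
import pytest

from bagmix.model import Dataset, GroupStructure, Hyperparameters, StateParameters
from bagmix.conditionals import ConditionalContext
from bagmix.gibbs import ChainConfig
from bagmix.diagnostics import replicate
from bagmix.synthetic import two_state_design

HARNESS_SEED = 20250901


@pytest.fixture(scope="session")
def harness_n100_prior1():
    """25-replication validation study at n=100 under the default prior:
    5000 Gibbs iterations per fit, 2500 burn-in, one chain."""
    return replicate(
        two_state_design(100), Hyperparameters.default(),
        ChainConfig(n_iter=5000, burn_in=2500, seed=HARNESS_SEED), R=25,
    )


@pytest.fixture(scope="session")
def harness_n100_prior2():
    """Same study under the alternative (more informative) prior."""
    return replicate(
        two_state_design(100), Hyperparameters.alternative(),
        ChainConfig(n_iter=5000, burn_in=2500, seed=HARNESS_SEED), R=25,
    )


@pytest.fixture(scope="session")
def harness_n300_prior1():
    """Reduced 5-replication study at n=300 (sample-size effect check)."""
    return replicate(
        two_state_design(300), Hyperparameters.default(),
        ChainConfig(n_iter=5000, burn_in=2500, seed=HARNESS_SEED), R=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20250927)


@pytest.fixture
def structure():
    return GroupStructure(L=2, group_sizes=(3, 3, 3))


@pytest.fixture
def small_dataset(rng):
    """Tiny single-state dataset with known coefficients, iid noise."""
    st = GroupStructure(L=2, group_sizes=(2,))
    N, T = 10, 2
    X = rng.standard_normal((N * T, st.n_coef))
    theta = np.array([1.0, -0.5, 2.0, 0.3])
    y = X @ theta + 0.5 * rng.standard_normal(N * T)
    return Dataset(
        y=y, X_alpha=X[:, :2], X_beta=X[:, 2:], structure=st, N=N, T=T
    )


def make_context(dataset, rng, params=None, hyper=None):
    """All rows assigned to one state."""
    st = dataset.structure
    if params is None:
        params = StateParameters.initial(st)
    if hyper is None:
        hyper = Hyperparameters.default()
    return ConditionalContext(
        X_alpha=dataset.X_alpha,
        X_beta=dataset.X_beta,
        y=dataset.y,
        params=params,
        hyper=hyper,
        rng=rng,
        group_slices=st.group_slices,
        group_sizes=st.group_sizes,
    )
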