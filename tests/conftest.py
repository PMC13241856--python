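import numpy as np
import pytest

from banditbfda import BFDACondition, PmfBank, TauGrid, fixture_small_task


@pytest.fixture(scope="session")
def coarse_grid():
    """60-point tau grid: same support as the default, faster for unit tests."""
    return TauGrid.default(lo=0.05, step=0.05)


@pytest.fixture(scope="session")
def full_grid():
    """The default 300-point tau grid."""
    return TauGrid.default()


@pytest.fixture(scope="session")
def full_bank(full_grid):
    """Session-wide PMF cache on the default grid (built lazily on use)."""
    return PmfBank(full_grid)


@pytest.fixture(scope="session")
def small_task():
    """Reduced horizon task (2 forced + 2 free trials, 16 paths)."""
    return fixture_small_task()


@pytest.fixture(scope="session")
def small_bank(coarse_grid):
    return PmfBank(coarse_grid)


@pytest.fixture
def small_condition(small_task, coarse_grid):
    """Cheap but complete BFDA condition on the reduced task."""

    def make(delta_mu=0.3, n_per_group=4, n_games=12, n_sims=6, seed=11, **kw):
        return BFDACondition(
            delta_mu=delta_mu,
            n_per_group=n_per_group,
            n_games=n_games,
            n_sims=n_sims,
            seed=seed,
            task=small_task,
            tau_grid=coarse_grid,
            **kw,
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
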