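"""Shared fixtures: small deterministic datasets and one quick reference fit."""

import numpy as np
import pytest

from rtscr import (
    CaptureData,
    Dataset,
    MCMCConfig,
    Priors,
    TruthParams,
    build_state_space,
    fit_rtscr,
    make_trap_grid,
    simulate_dataset,
)


@pytest.fixture
def small_traps():
    """3x3 grid, 1 km spacing, 5 occasions, all active."""
    return make_trap_grid(3, 3, 1000.0, n_occasions=5)


@pytest.fixture
def tiny_captures(small_traps):
    """Hand-sized capture data consistent with small_traps."""
    J, K = small_traps.n_traps, small_traps.n_occasions
    y_id = np.zeros((2, J, K), dtype=np.int64)
    y_id[0, 0, 0] = 2
    y_id[0, 4, 1] = 1
    y_id[1, 8, 3] = 1
    n_noid = np.zeros((J, K), dtype=np.int64)
    n_noid[4, 2] = 1
    n_noid[0, 4] = 2
    return CaptureData(y_id=y_id, n_noid=n_noid, individual_ids=["A", "B"])


@pytest.fixture
def tiny_dataset(small_traps, tiny_captures):
    space = build_state_space(small_traps, 2000.0)
    return Dataset(traps=small_traps, captures=tiny_captures, state_space=space)


# one moderately sized simulated dataset + fit shared by gof / summaries tests
_QUICK_TRUTH = TruthParams(n_true=15, lambda0=0.3, sigma=1500.0, theta=0.8, seed=11)


@pytest.fixture(scope="session")
def quick_sim():
    traps = make_trap_grid(4, 4, 1500.0, n_occasions=10)
    space = build_state_space(traps, 4500.0)
    return simulate_dataset(_QUICK_TRUTH, traps, space)


@pytest.fixture(scope="session")
def quick_fit(quick_sim):
    cfg = MCMCConfig(n_chains=3, n_iter=4000, n_burnin=1000, thin=5, seed=5)
    return fit_rtscr(quick_sim.dataset, priors=Priors(), config=cfg)
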