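import numpy as np
import pytest

from scovnet import RegionAtlas, SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def atlas():
    return RegionAtlas.default()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-parameter synthetic cohort (23 controls vs 24 patients)."""
    cohort, truth = generate_cohort(SimulationParams(seed=7))
    return cohort, truth


def random_adjacency(rng: np.random.Generator, n_nodes: int,
                     p_edge: float = 0.4) -> np.ndarray:
    """Random symmetric 0-diagonal boolean adjacency."""
    upper = rng.random((n_nodes, n_nodes)) < p_edge
    adj = np.triu(upper, k=1)
    return adj | adj.T
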