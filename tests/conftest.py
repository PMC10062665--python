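import numpy as np
import pytest

from moodpain.synthetic import CohortSpec, sticky_matrix


@pytest.fixture
def uniform4():
    return np.full((4, 4), 0.25)


@pytest.fixture
def two_component_spec():
    """Well-separated two-component cohort: stay probabilities 0.9 vs 0.5."""
    return CohortSpec(
        S=200,
        weights=np.array([0.5, 0.5]),
        matrices=np.stack([sticky_matrix(0.9), sticky_matrix(0.5)]),
        mean_length=40.0,
        seed=11,
    )


def random_regular_matrices(n_matrices: int, n: int = 4, seed: int = 0):
    """Strictly positive random row-stochastic matrices (hence regular)."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(n, 2.0), size=(n_matrices, n))
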