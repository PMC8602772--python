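import numpy as np
import pytest

from sca_deconv import CountMatrix, SimulationSpec, simulate_paired


@pytest.fixture(scope="session")
def small_pair():
    """A well-separated 3-group paired simulation at desk scale."""
    spec = SimulationSpec(
        n_genes=500,
        n_cells=210,
        group_proportions=(0.3, 0.4, 0.3),
        de_fac_scale=(0.8, 0.8, 0.8),
        seed=7,
    )
    return simulate_paired(spec)


@pytest.fixture(scope="session")
def small_labeled_counts(small_pair):
    """The true assay of the small simulation, with labels attached."""
    return small_pair.true_assay


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_counts(rng, n_genes=30, n_cells=12, lam=4.0, labels=None):
    values = rng.poisson(lam, size=(n_genes, n_cells))
    return CountMatrix(
        values,
        np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        np.array([f"c{j}" for j in range(n_cells)], dtype=object),
        labels,
    )
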