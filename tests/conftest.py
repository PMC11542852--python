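import numpy as np
import pytest

from mcadet.preprocess import CountMatrix, build_correspondence, fuzzy_code
from mcadet.synthetic import make_design, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """A 20 x 15 Poisson count matrix with no constant genes."""
    while True:
        Y = rng.poisson(2.0, size=(20, 15))
        if np.all(Y.max(axis=0) > Y.min(axis=0)):
            break
    return CountMatrix(
        values=Y,
        gene_ids=[f"g{j}" for j in range(15)],
        cell_ids=[f"c{i}" for i in range(20)],
    )


@pytest.fixture
def small_model(small_counts):
    Z, m1, m2 = fuzzy_code(small_counts)
    return build_correspondence(Z, m1, m2, small_counts.gene_ids, small_counts.cell_ids)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small, strongly separated simulated dataset for pipeline-level tests."""
    design = make_design(
        mode="coarse",
        level=20,
        seed=5,
        n_cells=400,
        n_genes=500,
        abundances=(0.5, 0.3, 0.2),
        drivers_per_pop=10,
        n_de=50,
    )
    design.baseline_median = 1.0  # well-expressed genes keep this fixture easy
    return design, simulate_counts(design)
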