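import numpy as np
import pytest
import scipy.sparse as sp

from nestde import CountMatrix, NestedDesign, simulate_scenario


@pytest.fixture
def toy_counts():
    """4 genes x 4 cells with hand-checkable values."""
    counts = np.array(
        [
            [1, 2, 3, 4],
            [0, 0, 0, 0],
            [5, 0, 0, 7],
            [2, 2, 2, 2],
        ]
    )
    return CountMatrix(
        sp.csr_matrix(counts),
        gene_ids=[f"g{i}" for i in range(4)],
        cell_ids=[f"c{i}" for i in range(4)],
    )


@pytest.fixture
def toy_design():
    """4 cells, 2 samples, 1 batch, 2 conditions."""
    return NestedDesign(
        cell_to_sample={"c0": "s1", "c1": "s1", "c2": "s2", "c3": "s2"},
        sample_to_batch={"s1": "b1", "s2": "b1"},
        sample_to_condition={"s1": "1", "s2": "2"},
    )


@pytest.fixture(scope="session")
def small_dataset_sim():
    """Reduced dataset-scenario simulation shared across tests."""
    return simulate_scenario("dataset", seed=42, overrides={"n_genes": 300})


@pytest.fixture(scope="session")
def small_negative_control_sim():
    """Reduced negative-control (no DE) simulation shared across tests."""
    return simulate_scenario("negative_control", seed=43, overrides={"n_genes": 300})


def gaussian_nested_matrix(
    n_genes, n_samples, cells_per_sample, sigma2_b, nu2_eps, seed
):
    """Gaussian two-level generator used as an independent oracle for ICC
    and variance arithmetic: y = b_sample + eps_cell per gene."""
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(sigma2_b), size=(n_genes, n_samples))
    x = np.repeat(b, cells_per_sample, axis=1) + rng.normal(
        0.0, np.sqrt(nu2_eps), size=(n_genes, n_samples * cells_per_sample)
    )
    cells = [f"c{i}" for i in range(n_samples * cells_per_sample)]
    design = NestedDesign(
        cell_to_sample={
            cells[i]: f"s{i // cells_per_sample}"
            for i in range(len(cells))
        },
        sample_to_batch={f"s{j}": "b1" for j in range(n_samples)},
        sample_to_condition={
            f"s{j}": ("1" if j < n_samples // 2 else "2") for j in range(n_samples)
        },
    )
    return x, design
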