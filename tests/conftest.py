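import numpy as np
import pytest

from scduet.expr_data import ExpressionMatrix
from scduet.synthetic_data import (
    SimulationConfig,
    simulate_two_types,
    spike_interaction_signature,
)

SMALL_CONFIG = SimulationConfig(
    n_cells_a=60,
    n_cells_b=60,
    n_genes=300,
    depth_a=20000.0,
    depth_b=2000.0,
    signature_genes=10,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-type simulation shared by fast tests."""
    matrix, truth = simulate_two_types(SMALL_CONFIG)
    return matrix, truth, SMALL_CONFIG


@pytest.fixture(scope="session")
def small_sim_split(small_sim):
    """The same simulation split into per-type matrices."""
    matrix, truth, cfg = small_sim
    is_a = truth.cell_type == "A"
    return (
        matrix.subset_cells(np.where(is_a)[0]),
        matrix.subset_cells(np.where(~is_a)[0]),
        truth,
        cfg,
    )


@pytest.fixture(scope="session")
def spiked_a_matrix():
    """Type-A cells with the interaction signature spiked in, plus truth."""
    matrix, truth = simulate_two_types(SMALL_CONFIG)
    spiked = spike_interaction_signature(matrix, truth, SMALL_CONFIG)
    is_a = truth.cell_type == "A"
    mat_a = spiked.subset_cells(np.where(is_a)[0])
    interacting_ids = set(spiked.cell_ids[truth.interacting])
    return mat_a, interacting_ids, truth, SMALL_CONFIG


def tiny_matrix(counts, prefix="c", gene_prefix="g", cell_type=None):
    counts = np.asarray(counts)
    return ExpressionMatrix(
        counts,
        cell_ids=[f"{prefix}{i}" for i in range(counts.shape[0])],
        gene_ids=[f"{gene_prefix}{j}" for j in range(counts.shape[1])],
        cell_type=cell_type,
    )
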