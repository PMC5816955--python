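import numpy as np
import pytest

from lbt2kit import synthio
from lbt2kit.io import CountMatrix


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation config shared across recovery tests."""
    return synthio.SimConfig(
        n_genes=2000,
        n_cells_per_condition=400,
        mean_depth_per_cell=4000.0,
        mean_depth_per_bulk_sample=2e6,
        phase_marker_counts=25,
        n_response_genes=40,
        seed=12,
    )


@pytest.fixture(scope="session")
def small_sc(small_config):
    matrices, truth = synthio.simulate_sc_counts(small_config)
    return matrices, truth


def make_counts(values, prefix="u") -> CountMatrix:
    values = np.asarray(values)
    return CountMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"{prefix}{j}" for j in range(values.shape[1])],
    )
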