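import numpy as np
import pytest

import scregulon as sr


SMALL = sr.SimulationConfig(
    n_genes=600,
    n_tfs=15,
    targets_per_tf=10,
    n_control_lines=2,
    n_case_lines=2,
    cells_per_line=150,
    n_clusters=6,
    seed=1,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale simulated dataset shared across tests (seed fixed)."""
    return sr.simulate_dataset(SMALL)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    counts, ann, truth = small_dataset
    filtered = sr.apply_qc(counts)
    norm = sr.normalize(filtered)
    ann = ann[ann["cell_id"].isin(set(filtered.cells))].reset_index(drop=True)
    return norm, ann, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
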