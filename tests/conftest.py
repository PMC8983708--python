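import warnings

import numpy as np
import pytest

from isocorde import CountMatrix, simulate_dataset

warnings.filterwarnings("ignore", message=".*zero-variance.*")
warnings.filterwarnings("ignore", message=".*pool .* exhausted.*")


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 isoforms (2 genes) x 8 cells over 2 cell types, hand-set counts."""
    values = np.array(
        [
            [10.0, 12.0, 8.0, 11.0, 0.0, 1.0, 0.0, 0.0],
            [1.0, 0.0, 2.0, 1.0, 9.0, 12.0, 10.0, 8.0],
            [5.0, 6.0, 4.0, 5.0, 5.0, 4.0, 6.0, 5.0],
        ]
    )
    return CountMatrix(
        values=values,
        isoform_ids=["iso_a1", "iso_a2", "iso_b1"],
        cell_ids=[f"c{j}" for j in range(8)],
        cell_types=["A"] * 4 + ["B"] * 4,
        gene_of={"iso_a1": "geneA", "iso_a2": "geneA", "iso_b1": "geneB"},
        length_of={"iso_a1": 1000.0, "iso_a2": 2000.0, "iso_b1": 4000.0},
    )


@pytest.fixture(scope="session")
def sim_small():
    """Scaled-down planted-module dataset (240 cells, 8 types, 15 modules)."""
    return simulate_dataset(
        n_cells=240, n_features=1500, per_module=30, top_n=210, seed=11
    )


@pytest.fixture(scope="session")
def sim_default():
    """The default study-condition simulation (1000 cells, 8 types,
    15 x 200 synthetic features, 1400-feature pools, refined at 0.75)."""
    return simulate_dataset(seed=1)
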