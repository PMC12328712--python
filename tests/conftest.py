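import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from cellmkl import RunConfig, make_dataset, run_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """Quick RNA fixture: strong signal in 2 of 6 groups, 150 cells."""
    return make_dataset(
        n_cells=150, n_groups=6, group_size=8, n_informative=2,
        effect=2.5, modality_plan="rna", seed=42,
    )


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """3-replicate experiment on the quick fixture (shared, read-only)."""
    ds = small_dataset
    return run_experiment(
        ds.matrices(), {"RNA": ds.gene_sets}, ds.labels,
        config=RunConfig(D=20), n_replicates=3, seed=7,
    )


@pytest.fixture(scope="session")
def multiome_dataset():
    """Small paired RNA+ATAC fixture with signal in both modalities."""
    return make_dataset(
        n_cells=120, n_groups=5, group_size=6, n_informative=2,
        effect=2.5, modality_plan="both", seed=99,
    )
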