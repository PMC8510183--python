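import numpy as np
import pandas as pd
import pytest

import storagefx as sx


@pytest.fixture(scope="session")
def default_dataset():
    """The full default synthetic storage experiment (seed 7)."""
    return sx.generate_dataset(seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced design for fast unit tests: 2 matrices, 2 temps, 50 genera."""
    design = sx.DesignSpec(
        matrices=("P1", "S1"),
        temperatures=(-80, 22),
        freeze_thaw_matrices=("P1", "S1"),
        n_genera=50,
        n_amr_genes=40,
        library_size=5e4,
    )
    return sx.generate_dataset(design=design, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_table(rng):
    """A random nonnegative count table, 12 features x 6 samples."""
    vals = rng.integers(0, 200, size=(12, 6)).astype(float)
    return pd.DataFrame(
        vals,
        index=[f"g{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(6)],
    )
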