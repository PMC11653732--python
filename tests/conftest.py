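import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    """3 samples x 4 taxa count table."""
    return pd.DataFrame(
        [[2, 2, 2, 2], [1, 3, 0, 4], [5, 0, 0, 5]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture
def random_table():
    """Factory for seeded random count tables."""

    def make(n_samples=12, n_taxa=20, seed=0, depth=50):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, depth, size=(n_samples, n_taxa))
        return pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )

    return make
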