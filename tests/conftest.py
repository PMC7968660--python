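import numpy as np
import pandas as pd
import pytest

from soilconet import CountTable, TaxonomyMap


@pytest.fixture
def small_table() -> CountTable:
    """3 taxa x 4 samples with one low-prevalence taxon."""
    df = pd.DataFrame(
        {
            "s1": [10, 0, 3],
            "s2": [5, 2, 0],
            "s3": [8, 1, 0],
            "s4": [2, 4, 0],
        },
        index=["t1", "t2", "t3"],
    )
    return CountTable(df.astype(np.int64))


@pytest.fixture
def taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        pd.Series(
            {"t1": "Actinobacteria", "t2": "Actinobacteria", "t3": "Proteobacteria"},
            name="phylum",
        )
    )


def random_count_table(rng: np.random.Generator, n_taxa=None, n_samples=None) -> CountTable:
    n_taxa = n_taxa or int(rng.integers(2, 8))
    n_samples = n_samples or int(rng.integers(2, 6))
    counts = rng.integers(0, 50, size=(n_taxa, n_samples))
    df = pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CountTable(df.astype(np.int64))
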