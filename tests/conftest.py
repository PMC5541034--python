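import numpy as np
import pandas as pd
import pytest

from rumicol.community import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_table():
    """Factory for small count tables from a plain array."""

    def _make(arr, samples=None, taxa=None, rank="genus"):
        arr = np.asarray(arr)
        samples = samples or [f"s{i}" for i in range(arr.shape[0])]
        taxa = taxa or [f"g__T{j}" for j in range(arr.shape[1])]
        return CountTable(pd.DataFrame(arr, index=samples, columns=taxa), rank=rank)

    return _make


@pytest.fixture
def random_table(rng, make_table):
    def _make(n_samples=8, n_taxa=12, low=0, high=60, seed=None):
        r = rng if seed is None else np.random.default_rng(seed)
        return make_table(r.integers(low, high, size=(n_samples, n_taxa)))

    return _make
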