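import numpy as np
import pandas as pd
import pytest

from arrestseq import synthgen


@pytest.fixture(scope="session")
def ts_small():
    """Small time-series dataset for fast unit tests."""
    design = synthgen.default_timeseries_design(library_depth=200_000)
    return synthgen.simulate_timeseries(n_genes=300, design=design, seed=11)


@pytest.fixture(scope="session")
def aid_small():
    """Small perturbation dataset for fast unit tests."""
    design = synthgen.default_aid_design(library_depth=300_000)
    return synthgen.simulate_aid(n_genes=400, design=design, seed=5)


@pytest.fixture(scope="session")
def ts_default():
    """Default-scale time series (2000 genes, depth 1e6, seed 1)."""
    return synthgen.simulate_timeseries(n_genes=2000, seed=1)


@pytest.fixture(scope="session")
def aid_default():
    """Default-scale perturbation dataset (2000 genes, depth 1e6, seed 1)."""
    return synthgen.simulate_aid(n_genes=2000, seed=1)


@pytest.fixture
def toy_counts():
    """Tiny deterministic count matrix with two spike rows."""
    data = {
        "s1": [100, 0, 50, 30, 20, 10],
        "s2": [200, 0, 100, 60, 40, 20],
        "s3": [90, 5, 55, 25, 15, 12],
    }
    idx = ["gene1", "gene2", "gene3", "gene4", "ERCC-00001", "ERCC-00002"]
    return pd.DataFrame(data, index=idx)
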