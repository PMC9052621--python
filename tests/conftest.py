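import numpy as np
import pandas as pd
import pytest

from stemsig.containers import ExpressionMatrix
from stemsig.simulate import ScrnaSimSpec, simulate_scrna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_bulk(rng):
    """A 20-gene x 8-sample bulk matrix on a log-like scale."""
    x = rng.normal(5.0, 2.0, size=(20, 8))
    return ExpressionMatrix(
        x,
        pd.Index([f"g{i}" for i in range(20)]),
        pd.Index([f"s{j}" for j in range(8)]),
        orientation="genes_by_samples",
        layer_tag="tpm_like",
    )


@pytest.fixture(scope="session")
def small_scrna():
    """One small simulated single-cell dataset plus its truth tables."""
    spec = ScrnaSimSpec(n_cells=400, n_genes=300, seed=11)
    return simulate_scrna(spec)
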