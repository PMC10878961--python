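import numpy as np
import pandas as pd
import pytest

from iersig import ExpressionMatrix


@pytest.fixture
def toy_counts():
    """3 genes x 2 samples counts with means 1, 4, 0 (filter threshold = 2)."""
    return ExpressionMatrix(
        ["gA", "gB", "gC"], ["s1", "s2"],
        np.array([[1.0, 1.0], [4.0, 4.0], [0.0, 0.0]]),
        "counts",
    )


@pytest.fixture
def log_cells():
    """Small log-normalized matrix for per-cell scoring tests."""
    rng = np.random.default_rng(0)
    values = np.log1p(rng.poisson(5.0, size=(30, 12)).astype(float))
    return ExpressionMatrix(
        [f"g{i}" for i in range(30)], [f"c{j}" for j in range(12)],
        values, "log_normalized",
    )


@pytest.fixture
def meta_matrix():
    """Normalized 6-sample matrix with batch metadata for ranking tests."""
    rng = np.random.default_rng(1)
    values = rng.lognormal(3.0, 0.5, size=(20, 6))
    meta = pd.DataFrame(
        {"batch": ["b1", "b1", "b1", "b2", "b2", "b2"]},
        index=pd.Index([f"s{j}" for j in range(6)]),
    )
    return ExpressionMatrix(
        [f"g{i}" for i in range(20)], [f"s{j}" for j in range(6)],
        values, "normalized", meta,
    )
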