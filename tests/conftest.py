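import numpy as np
import pytest

from crn import DataKind, EdgeScoreMatrix, ExpressionDataset, GoldStandard


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_ts_dataset(rng):
    """6 genes x 12 time points of smooth positive expression values."""
    values = np.cumsum(rng.uniform(-0.3, 0.35, size=(6, 12)), axis=1) + 2.0
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(1, 7)],
        values=values,
        kind=DataKind.TIME_SERIES,
    )


@pytest.fixture
def small_ss_dataset(rng):
    values = rng.uniform(0.5, 3.0, size=(5, 8))
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(1, 6)],
        values=values,
        kind=DataKind.STEADY_STATE,
    )


def random_similarity_matrix(rng, m, zero_frac=0.0):
    """Random symmetric nonnegative score matrix with NaN diagonal."""
    a = rng.uniform(0.05, 1.0, size=(m, m))
    s = (a + a.T) / 2.0
    if zero_frac:
        mask = rng.random((m, m)) < zero_frac
        mask = mask | mask.T
        s[mask] = 0.0
    np.fill_diagonal(s, np.nan)
    return EdgeScoreMatrix(
        gene_ids=[f"g{i}" for i in range(m)], scores=s, symmetric=True
    )


@pytest.fixture
def toy_gold():
    """3 genes, single true link g1 -> g2."""
    return GoldStandard(gene_ids=["g1", "g2", "g3"], present={("g1", "g2")})
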