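import numpy as np
import pandas as pd
import pytest

from osap.expression_io import ExpressionMatrix, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    """4 genes x 3 samples with distinct values."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array([
            [4.0, 1.0, 2.0],
            [3.0, 2.0, 8.0],
            [2.0, 3.0, 5.0],
            [1.0, 4.0, 3.0],
        ]),
    )


@pytest.fixture
def random_matrix(rng):
    n_genes, n_samples = 50, 5
    return ExpressionMatrix(
        gene_ids=[f"g{i:03d}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        values=rng.normal(8.0, 2.0, size=(n_genes, n_samples)),
    )


@pytest.fixture
def two_group_table():
    ids = [f"case{i}" for i in range(4)] + [f"ctrl{i}" for i in range(4)]
    return SampleTable(pd.DataFrame(
        {"group": ["case"] * 4 + ["control"] * 4, "cohort": "c1"},
        index=pd.Index(ids, name="sample_id"),
    ))
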