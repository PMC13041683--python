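import numpy as np
import pandas as pd
import pytest

from txdiv import ExpressionMatrix, GroupDesign, tpm_from_counts


@pytest.fixture
def small_counts():
    """3 genes x 4 samples, two groups, hand-sized."""
    return pd.DataFrame(
        {
            "a1": [10, 10, 0],
            "a2": [8, 12, 0],
            "b1": [2, 10, 8],
            "b2": [4, 8, 8],
        },
        index=["g1", "g2", "g3"],
        dtype=float,
    )


@pytest.fixture
def small_matrix(small_counts):
    m = ExpressionMatrix(
        counts=small_counts,
        gene_lengths=pd.Series([1000.0, 1000.0, 1000.0], index=small_counts.index),
    )
    return tpm_from_counts(m)


@pytest.fixture
def small_design():
    return GroupDesign(
        assignments=pd.Series(
            {"a1": "ctrl", "a2": "ctrl", "b1": "case", "b2": "case"}
        ),
        groups=["ctrl", "case"],
        control="ctrl",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tpm_matrix(rng, n_genes=50, n_samples=6, zero_frac=0.2):
    """Random TPM table with some structural zeros, columns summing to 1e6."""
    x = rng.lognormal(0, 1.5, (n_genes, n_samples))
    x[rng.random((n_genes, n_samples)) < zero_frac] = 0.0
    x[0, :] = np.maximum(x[0, :], 1.0)  # keep every column nonzero
    x[1, :] = np.maximum(x[1, :], 1.0)
    tpm = x / x.sum(axis=0) * 1e6
    return pd.DataFrame(
        tpm,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
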