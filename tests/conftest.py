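import numpy as np
import pandas as pd
import pytest

from azenet.expression import ExpressionMatrix


def make_matrix(values, n1, n2, gene_prefix="g", kind="counts", tfs=()):
    """Small ExpressionMatrix helper: `values` is genes x (n1 + n2)."""
    values = np.asarray(values, dtype=float)
    genes = [f"{gene_prefix}{i}" for i in range(values.shape[0])]
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    cond = pd.Series([1] * n1 + [2] * n2, index=samples)
    is_tf = pd.Series([g in set(tfs) for g in genes], index=genes)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        condition=cond,
        is_tf=is_tf,
        kind=kind,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_correlation(rng, n, m_obs=8):
    """Valid correlation matrix from a random data matrix."""
    x = rng.standard_normal((m_obs, n))
    c = np.corrcoef(x.T)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c
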