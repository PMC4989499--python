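import numpy as np
import pandas as pd
import pytest

from wavecrest import ExpressionMatrix, RescaledMatrix


def make_expression(values, labels, levels=None, unit="counts", genes=None, cells=None):
    """Build an ExpressionMatrix from a raw array and per-cell labels."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{j}" for j in range(n_cells)]
    levels = levels or list(dict.fromkeys(labels))
    time = pd.Series(
        pd.Categorical(labels, categories=levels, ordered=True), index=cells
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cells), time, unit)


def make_rescaled(values, labels, levels=None, genes=None, cells=None):
    """Build a RescaledMatrix directly from an already-standardized array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{j}" for j in range(n_cells)]
    levels = levels or list(dict.fromkeys(labels))
    time = pd.Series(
        pd.Categorical(labels, categories=levels, ordered=True), index=cells
    )
    return RescaledMatrix(
        values=pd.DataFrame(values, index=genes, columns=cells),
        time=time,
        gene_means=pd.Series(0.0, index=genes),
        gene_sds=pd.Series(1.0, index=genes),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
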