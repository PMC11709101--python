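import numpy as np
import pytest
import scipy.sparse as sp

from senmap.io import ExpressionMatrix, SpotGrid


def make_matrix(counts, gene_ids=None, cell_ids=None, lognorm=None):
    """ExpressionMatrix from a dense array, optionally with a forced lognorm
    layer (for analytically constructed examples)."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    m = ExpressionMatrix(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=cell_ids or [f"c{j}" for j in range(n_cells)],
        counts=sp.csr_matrix(counts),
    )
    if lognorm is not None:
        m.lognorm = sp.csr_matrix(np.asarray(lognorm, dtype=float))
    return m


def make_grid(coords, expr=None, gene="CDKN1A", sample_id="test"):
    """SpotGrid from (row, col) pairs with optional per-spot expression."""
    import pandas as pd

    rows = np.array([r for r, _ in coords])
    cols = np.array([c for _, c in coords])
    ids = [f"s{r}x{c}" for r, c in coords]
    e = pd.DataFrame({gene: expr}, index=pd.Index(ids, name="spot_id")) if expr is not None else pd.DataFrame()
    return SpotGrid(spot_ids=ids, array_row=rows, array_col=cols, expr=e, sample_id=sample_id)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def grid_factory():
    return make_grid
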