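"""Labelled genes x cells matrix container.

The pipeline keeps matrices gene-major (genes as rows, cells as columns),
matching the 10x Matrix-Market on-disk layout. Raw counts are integer-valued;
:func:`scregulon.qc.normalize` returns the same container holding reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InputError


@dataclass
class GeneMatrix:
    """A genes x cells expression matrix with gene and cell identifiers.

    Parameters
    ----------
    X
        Sparse matrix of shape ``(n_genes, n_cells)``. Stored as CSR.
    genes
        Gene identifiers, one per row; must be unique.
    cells
        Cell identifiers (barcodes), one per column; must be unique.
    """

    X: sp.csr_matrix
    genes: pd.Index = field()
    cells: pd.Index = field()

    def __post_init__(self) -> None:
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X))
        else:
            self.X = self.X.tocsr()
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.X.shape != (len(self.genes), len(self.cells)):
            raise InputError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.genes.has_duplicates:
            raise InputError("duplicate gene identifiers")
        if self.cells.has_duplicates:
            raise InputError("duplicate cell identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_genes(self, names) -> "GeneMatrix":
        """Return the sub-matrix restricted to ``names`` (order as given)."""
        idx = self.genes.get_indexer(pd.Index(names))
        if (idx < 0).any():
            missing = pd.Index(names)[idx < 0].tolist()
            raise InputError(f"genes not in matrix: {missing[:10]}")
        return GeneMatrix(self.X[idx, :], pd.Index(names), self.cells)

    def subset_cells(self, names) -> "GeneMatrix":
        """Return the sub-matrix restricted to cells ``names`` (order as given)."""
        idx = self.cells.get_indexer(pd.Index(names))
        if (idx < 0).any():
            missing = pd.Index(names)[idx < 0].tolist()
            raise InputError(f"cells not in matrix: {missing[:10]}")
        return GeneMatrix(self.X[:, idx], self.genes, pd.Index(names))

    def row(self, gene: str) -> np.ndarray:
        """Dense expression vector of one gene across all cells."""
        i = self.genes.get_loc(gene)
        return np.asarray(self.X[i, :].todense()).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def copy(self) -> "GeneMatrix":
        return GeneMatrix(self.X.copy(), self.genes.copy(), self.cells.copy())
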