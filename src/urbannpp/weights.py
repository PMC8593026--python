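"""Sparse spatial weights over fishnet cells.

Queen (8-neighbor) and rook (4-neighbor) contiguity on the cell lattice,
plus k-nearest-neighbor weights on cell centers. Contiguity weights are
symmetric binary before optional row standardization. The Cliff-Ord sums
W0, S1, S2 feeding the Moran variance formulas are exposed as properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .fishnet import FishnetGrid

logger = logging.getLogger(__name__)

_QUEEN_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK_OFFSETS = [(-1, 0), (1, 0), (0, -1), (0, 1)]


@dataclass
class SpatialWeights:
    """Sparse neighbor structure w_ij with no self-neighbors (w_ii = 0)."""

    W: sparse.csr_matrix
    scheme: str
    standardization: str
    ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.W = sparse.csr_matrix(self.W)
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("weights matrix must be square")
        if self.ids is None:
            self.ids = np.arange(self.W.shape[0])

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def cardinalities(self) -> np.ndarray:
        return np.diff(self.W.indptr)

    @property
    def islands(self) -> np.ndarray:
        """Indices of cells with no neighbors."""
        return np.flatnonzero(self.cardinalities == 0)

    @property
    def W0(self) -> float:
        return float(self.W.sum())

    @property
    def S1(self) -> float:
        A = self.W + self.W.T
        return float(0.5 * A.multiply(A).sum())

    @property
    def S2(self) -> float:
        r = np.asarray(self.W.sum(axis=1)).ravel() + np.asarray(self.W.sum(axis=0)).ravel()
        return float((r ** 2).sum())


def build_weights(
    grid: FishnetGrid,
    scheme: str = "queen",
    standardization: str = "row",
    k: int = 8,
) -> SpatialWeights:
    """Build spatial weights over the valid cells of a fishnet grid.

    ``scheme`` is 'queen' (8-neighborhood on the lattice), 'rook'
    (4-neighborhood) or 'knn' (k nearest cell centers, asymmetric).
    ``standardization`` is 'row' (each nonempty row sums to 1) or 'binary'.
    """
    n = grid.n
    if n < 2:
        raise ValueError(f"at least 2 valid cells required, got {n}")
    if scheme in ("queen", "rook"):
        offsets = _QUEEN_OFFSETS if scheme == "queen" else _ROOK_OFFSETS
        rows = grid.table["row"].to_numpy(dtype=int)
        cols = grid.table["col"].to_numpy(dtype=int)
        index_of = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
        ii, jj = [], []
        for i, (r, c) in enumerate(zip(rows, cols)):
            for dr, dc in offsets:
                j = index_of.get((r + dr, c + dc))
                if j is not None:
                    ii.append(i)
                    jj.append(j)
        W = sparse.csr_matrix(
            (np.ones(len(ii)), (ii, jj)), shape=(n, n), dtype=float
        )
    elif scheme == "knn":
        if k < 1 or k >= n:
            raise ValueError(f"knn requires 1 <= k < n, got k={k}, n={n}")
        tree = cKDTree(grid.coords)
        _, nbr = tree.query(grid.coords, k=k + 1)
        nbr = np.atleast_2d(nbr)[:, 1:]  # drop self
        ii = np.repeat(np.arange(n), k)
        W = sparse.csr_matrix(
            (np.ones(n * k), (ii, nbr.ravel())), shape=(n, n), dtype=float
        )
    else:
        raise ValueError(f"unknown weights scheme {scheme!r}")

    W.setdiag(0.0)
    W.eliminate_zeros()

    card = np.diff(W.indptr)
    n_islands = int((card == 0).sum())
    if n_islands == n:
        raise ValueError("all cells are isolated; cannot build spatial weights")
    if n_islands:
        logger.warning("spatial weights: %d island cell(s) with no neighbors", n_islands)

    if standardization == "row":
        rowsum = np.asarray(W.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        W = sparse.diags(inv) @ W
    elif standardization != "binary":
        raise ValueError(f"unknown standardization {standardization!r}")

    return SpatialWeights(
        W=sparse.csr_matrix(W),
        scheme=scheme,
        standardization=standardization,
        ids=grid.table["id"].to_numpy(),
    )


def lattice_weights(
    nrows: int, ncols: int, scheme: str = "queen", standardization: str = "row"
) -> SpatialWeights:
    """Weights for a full rectangular lattice (convenience for tests/nulls)."""
    import pandas as pd

    rows, cols = np.divmod(np.arange(nrows * ncols), ncols)
    table = pd.DataFrame(
        {"id": np.arange(nrows * ncols), "row": rows, "col": cols,
         "u": cols + 0.5, "v": nrows - rows - 0.5}
    )
    grid = FishnetGrid(table=table, cell_size=1.0, crs="EPSG:32648",
                       nrows=nrows, ncols=ncols, origin=(0.0, float(nrows)))
    return build_weights(grid, scheme=scheme, standardization=standardization)
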