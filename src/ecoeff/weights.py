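"""Spatial weight matrices: container, file formats (dense CSV, GAL) and
row standardization.

A spatial weight matrix W is an n x n nonnegative matrix with zero diagonal
encoding which regions are neighbours of which; its row-standardized form
(each nonzero row rescaled to sum to one) is what the spatial-lag operator,
Moran's I and the spatial Durbin model consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger("ecoeff.weights")

__all__ = ["SpatialWeights", "read_weights", "write_gal", "row_standardize", "spatial_lag"]


@dataclass
class SpatialWeights:
    """Ordered region ids plus the weight matrix itself.

    Parameters
    ----------
    ids : list of str
        Region identifiers, in matrix row/column order.
    w : ndarray of shape (n, n)
        Nonnegative weights, zero diagonal.
    standardized : bool
        True once each nonzero row sums to one.
    """

    ids: list
    w: np.ndarray
    standardized: bool = False
    zero_rows: list = field(default_factory=list)

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        n = len(self.ids)
        if self.w.shape != (n, n):
            raise FormatError(
                f"weight matrix shape {self.w.shape} does not match {n} region ids"
            )
        if (self.w < 0).any():
            raise DomainError("negative spatial weight")
        if np.diag(self.w).any():
            logger.warning("nonzero diagonal in weight matrix; zeroing it")
            np.fill_diagonal(self.w, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W (row-standardized contiguity matrices are
        similar to a symmetric matrix, so the spectrum is real)."""
        ev = np.linalg.eigvals(self.w)
        if np.abs(ev.imag).max() > 1e-8:
            raise DomainError("weight matrix has genuinely complex eigenvalues")
        return np.sort(ev.real)

    def rho_interval(self) -> tuple:
        """Stability interval (1/lambda_min, 1/lambda_max) of the spatial
        autoregressive parameter."""
        ev = self.eigenvalues()
        lo = 1.0 / ev[0] if ev[0] < 0 else -np.inf
        hi = 1.0 / ev[-1] if ev[-1] > 0 else np.inf
        return lo, hi


def read_weights(path, fmt: str | None = None) -> SpatialWeights:
    """Read a spatial weight matrix from a dense CSV or a GAL neighbour list.

    Dense CSV: square table, first column = region id, header row = region
    ids. GAL: the classic text format (header line ``n``, then pairs of
    ``id k`` / neighbour lines); converted to symmetric binary contiguity.
    """
    path = str(path)
    if fmt is None:
        fmt = "gal" if path.lower().endswith(".gal") else "dense-csv"
    if fmt in ("gal", "GAL"):
        return _read_gal(path)
    if fmt in ("dense-csv", "csv", "dense"):
        return _read_dense_csv(path)
    raise FormatError(f"unknown weights format {fmt!r}")


def _read_dense_csv(path) -> SpatialWeights:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"dense weight matrix must be square, got {df.shape}")
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if cols != ids:
        # accept any column order if the label sets agree
        if sorted(cols) != sorted(ids):
            raise FormatError("row and column labels of dense weight matrix differ")
        df = df[list(df.index)]
    return SpatialWeights(ids=ids, w=df.to_numpy(dtype=float))


def _read_gal(path) -> SpatialWeights:
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise FormatError("empty GAL file")
    header = tokens_by_line[0]
    # GAL headers are either "n" or "0 n file var"; n is the last plausible int
    try:
        n = int(header[0]) if len(header) == 1 else int(header[1])
    except ValueError as exc:
        raise FormatError(f"unreadable GAL header {header!r}") from exc
    ids: list = []
    neigh: dict = {}
    i = 1
    while i < len(tokens_by_line):
        head = tokens_by_line[i]
        if len(head) != 2:
            raise FormatError(f"expected 'id n_neighbours' line, got {head!r}")
        rid, k = head[0], int(head[1])
        if k > 0:
            if i + 1 >= len(tokens_by_line):
                raise FormatError(f"GAL file truncated after region {rid}")
            nbrs = tokens_by_line[i + 1]
            if len(nbrs) != k:
                raise FormatError(
                    f"region {rid} declares {k} neighbours but lists {len(nbrs)}"
                )
            i += 2
        else:
            nbrs = []
            i += 1
        ids.append(rid)
        neigh[rid] = nbrs
    if len(ids) != n:
        raise FormatError(f"GAL header declares {n} regions, file defines {len(ids)}")
    index = {r: j for j, r in enumerate(ids)}
    w = np.zeros((n, n))
    for rid, nbrs in neigh.items():
        for nb in nbrs:
            if nb not in index:
                raise FormatError(f"neighbour {nb!r} of {rid!r} is not a region id")
            w[index[rid], index[nb]] = 1.0
            w[index[nb], index[rid]] = 1.0  # symmetric binary contiguity
    np.fill_diagonal(w, 0.0)
    return SpatialWeights(ids=ids, w=w)


def write_gal(weights: SpatialWeights, path) -> None:
    """Write binary contiguity (w > 0) as a GAL neighbour list."""
    with open(path, "w") as fh:
        fh.write(f"{weights.n}\n")
        for i, rid in enumerate(weights.ids):
            nbrs = [weights.ids[j] for j in np.nonzero(weights.w[i])[0]]
            fh.write(f"{rid} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(str(x) for x in nbrs) + "\n")


def row_standardize(weights: SpatialWeights) -> SpatialWeights:
    """Divide each nonzero row by its sum; zero rows (isolates) are left
    untouched and collected in ``zero_rows``. Idempotent."""
    w = weights.w.copy()
    sums = w.sum(axis=1)
    zero = sums == 0
    nz = ~zero
    w[nz] = w[nz] / sums[nz, None]
    zero_ids = [weights.ids[i] for i in np.nonzero(zero)[0]]
    if zero_ids:
        logger.warning("isolated regions with no neighbours: %s", zero_ids)
    return SpatialWeights(
        ids=list(weights.ids), w=w, standardized=True, zero_rows=zero_ids
    )


def spatial_lag(x, weights: SpatialWeights) -> np.ndarray:
    """Spatial lag (Wx)_i = sum_j w_ij x_j. With row-standardized W this is
    the neighbourhood average, so the lag of a constant is that constant."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != weights.n:
        raise DomainError(
            f"value vector length {x.shape[0]} does not match {weights.n} regions"
        )
    return weights.w @ x
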