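"""Spatial weight matrices: construction, validation, file round-trip.

A spatial autoregressive (SAR) model couples cross-sectional units through
an N x N weight matrix W with zero diagonal and nonnegative entries.  The
Monte Carlo designs in this package use the classic row-normalized
group-interaction ("block") matrix: units are partitioned into groups of
equal size m, every unit interacts equally with the other m-1 members of
its group, and rows sum to one, i.e.

    W = I_{N/m} (x) (J_m - I_m) / (m - 1)

where J_m is the m x m all-ones matrix.  Row-stochasticity guarantees that
I - rho*W is invertible for every |rho| < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpatialWeightMatrix",
    "build_block_weights",
    "validate_weights",
    "read_weights",
    "write_weights",
]

#: A-priori bound on absolute row/column sums considered "bounded".
ROWSUM_BOUND = 10.0


@dataclass(frozen=True)
class SpatialWeightMatrix:
    """N x N nonnegative spatial weights with zero diagonal.

    Attributes
    ----------
    values : ndarray of shape (N, N)
        The weights themselves (dimensionless).
    row_normalized : bool
        Whether every nonzero row sums to one.
    """

    values: np.ndarray
    row_normalized: bool = field(default=False)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    def spatial_lag(self, y: np.ndarray) -> np.ndarray:
        """Return W @ y along the unit axis; y has shape (N,) or (N, T)."""
        return self.values @ y


def build_block_weights(n_units: int, block_size: int = 10) -> SpatialWeightMatrix:
    """Row-normalized block (group-interaction) weight matrix.

    Parameters
    ----------
    n_units : int
        Total number of units N; must be a positive multiple of ``block_size``.
    block_size : int
        Group size m (default 10, the replication design).

    Returns
    -------
    SpatialWeightMatrix
        Block-diagonal with N/m identical blocks (J_m - I_m)/(m-1).
    """
    if block_size < 2:
        raise ValueError("block_size must be at least 2")
    if n_units < block_size or n_units % block_size != 0:
        raise ValueError(
            f"n_units={n_units} must be a positive multiple of the block size "
            f"{block_size} (group-interaction design)"
        )
    block = (np.ones((block_size, block_size)) - np.eye(block_size)) / (block_size - 1)
    values = np.kron(np.eye(n_units // block_size), block)
    return SpatialWeightMatrix(values=values, row_normalized=True)


def validate_weights(w: SpatialWeightMatrix | np.ndarray,
                     rowsum_bound: float = ROWSUM_BOUND) -> list[str]:
    """Check the weight-matrix invariants; return a list of violations.

    An empty list means the matrix is a valid spatial weight matrix:
    square, zero diagonal, nonnegative, with absolute row and column sums
    bounded by ``rowsum_bound``, and (if flagged row-normalized) nonzero
    rows summing to one within 1e-12.
    """
    if isinstance(w, SpatialWeightMatrix):
        values = w.values
        row_normalized = w.row_normalized
    else:
        values = np.asarray(w, dtype=float)
        row_normalized = False
    report: list[str] = []
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        report.append(f"matrix is not square: shape {values.shape}")
        return report
    if not np.all(np.isfinite(values)):
        report.append("non-finite weight entries")
        return report
    if np.any(np.diag(values) != 0):
        report.append("nonzero diagonal entries")
    if np.any(values < 0):
        report.append("negative weight entries")
    rs = np.abs(values).sum(axis=1).max(initial=0.0)
    cs = np.abs(values).sum(axis=0).max(initial=0.0)
    if rs > rowsum_bound:
        report.append(f"maximum absolute row sum {rs:.3g} exceeds bound {rowsum_bound}")
    if cs > rowsum_bound:
        report.append(f"maximum absolute column sum {cs:.3g} exceeds bound {rowsum_bound}")
    if row_normalized:
        sums = values.sum(axis=1)
        nonzero = np.abs(values).sum(axis=1) > 0
        if np.any(np.abs(sums[nonzero] - 1.0) > 1e-12):
            report.append("row_normalized flag set but some nonzero row does not sum to 1")
    return report


def read_weights(path: str | Path) -> SpatialWeightMatrix:
    """Read a weight matrix from dense CSV (no header) or matrix-market MTX.

    The format is detected from the file extension (.mtx / .mm are treated
    as matrix-market, anything else as dense CSV).
    """
    path = Path(path)
    if path.suffix.lower() in (".mtx", ".mm"):
        from scipy.io import mmread

        m = mmread(path)
        values = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
    else:
        values = np.loadtxt(path, delimiter=",", dtype=float, ndmin=2)
    rows = values.sum(axis=1)
    nonzero = np.abs(values).sum(axis=1) > 0
    row_normalized = bool(np.all(np.abs(rows[nonzero] - 1.0) <= 1e-12)) and nonzero.any()
    return SpatialWeightMatrix(values=values, row_normalized=row_normalized)


def write_weights(w: SpatialWeightMatrix, path: str | Path) -> None:
    """Write a weight matrix as dense CSV (no header) or matrix-market MTX."""
    path = Path(path)
    if path.suffix.lower() in (".mtx", ".mm"):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(path, csr_matrix(w.values))
    else:
        np.savetxt(path, w.values, delimiter=",")
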