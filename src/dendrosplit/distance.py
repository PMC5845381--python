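"""Cell-cell distance matrices.

The default metric for expression data is the correlation distance
d(x, y) = 1 - r(x, y), with r the Pearson correlation, bounded in [0, 2]
and invariant to per-cell shift and positive rescaling. Euclidean distance
is provided for low-dimensional geometric data; precomputed matrices are
validated and passed through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import ExpressionMatrix

METRICS = ("correlation", "euclidean")


@dataclass
class DistanceMatrix:
    """A symmetric N x N matrix of pairwise cell distances."""

    values: np.ndarray
    cell_ids: list[str]
    metric_name: str = "correlation"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.validate()

    def validate(self) -> None:
        v = self.values
        n = len(self.cell_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix entries must be finite")
        if v.size and v.min() < 0:
            raise ValueError("distances must be non-negative")
        if not np.array_equal(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if self.metric_name == "correlation" and v.size and v.max() > 2:
            raise ValueError("correlation distances must be <= 2")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def submatrix(self, index: np.ndarray) -> np.ndarray:
        index = np.asarray(index)
        return self.values[np.ix_(index, index)]


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation between two expression vectors, in [0, 2].

    A zero-variance (constant) vector has no defined correlation; by
    convention its distance is 0 to an identical constant vector and 1 to
    anything else, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("vectors must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(xc @ xc))
    ny = float(np.sqrt(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        warnings.warn(
            "correlation undefined for a constant vector; using convention "
            "d=0 for identical vectors, d=1 otherwise",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0 if np.array_equal(x, y) else 1.0
    r = float(xc @ yc) / (nx * ny)
    return float(np.clip(1.0 - r, 0.0, 2.0))


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    const = norms == 0
    safe = np.where(const, 1.0, norms)
    z = centered / safe[:, None]
    d = 1.0 - z @ z.T
    np.clip(d, 0.0, 2.0, out=d)
    if const.any():
        warnings.warn(
            "constant expression vectors found; their correlation distance "
            "is set to 1 (0 against an identical constant vector)",
            RuntimeWarning,
            stacklevel=3,
        )
        idx = np.flatnonzero(const)
        d[idx, :] = 1.0
        d[:, idx] = 1.0
        for i in idx:
            same = np.all(values == values[i], axis=1)
            d[i, same] = 0.0
            d[same, i] = 0.0
    return d


def distance_matrix(X: ExpressionMatrix, metric: str = "correlation") -> DistanceMatrix:
    """Compute all pairwise cell-cell distances for an expression matrix.

    The upper triangle is mirrored onto the lower one so the result is
    exactly symmetric, and the diagonal is exactly zero.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if X.n_cells < 2:
        raise ValueError("need at least 2 cells for a distance matrix")
    if metric == "correlation":
        d = _correlation_matrix(X.values)
    else:
        d = squareform(pdist(X.values, metric="euclidean"))
    d = np.triu(d, k=1)
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, cell_ids=list(X.cell_ids), metric_name=metric)


def upper_triangle(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Strictly-upper-triangle entries of a square matrix (each pair once)."""
    v = D.values if isinstance(D, DistanceMatrix) else np.asarray(D)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def distance_percentile(D: DistanceMatrix, q: float) -> float:
    """The q-th percentile of the off-diagonal pairwise distances.

    Only the strictly-upper triangle enters (each unordered pair counted
    once, zero diagonal excluded); linear interpolation between order
    statistics.
    """
    if not 0 <= q <= 100:
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(upper_triangle(D), q))
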