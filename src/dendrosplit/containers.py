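"""Core in-memory containers: expression matrices and label vectors.

The cells x genes orientation is fixed throughout the package: rows are
cells, columns are genes, matching the N x M convention of the clustering
algorithm. All readers normalise to this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel label for a cell left without a cluster during the split step.
SINGLETON = "Singleton"
#: Sentinel label for a singleton whose nearest clustered neighbour is too far.
UNCLASSIFIED = "Unclassified"
SENTINELS = frozenset({SINGLETON, UNCLASSIFIED})


@dataclass
class ExpressionMatrix:
    """An N x M expression matrix with cell and gene identifiers.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` float array. Entries must be finite,
        and non-negative while ``log_transformed`` is False.
    cell_ids, gene_ids
        Unique identifiers for rows and columns respectively.
    log_transformed
        True once values are on the log10(x+1) analysis scale. Also used
        to mark matrices whose values are already on the final analysis
        scale (e.g. 2-D geometric coordinates), which may be negative and
        must not be transformed again.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"{n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.gene_ids):
            raise ValueError(
                f"{m} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be pairwise distinct")
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be pairwise distinct")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        if not self.log_transformed and self.values.size and self.values.min() < 0:
            raise ValueError("raw expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        """Restrict to the cells selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[index, :],
            cell_ids=[self.cell_ids[i] for i in index],
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Restrict to the genes selected by a boolean mask or index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[:, index],
            gene_ids=[self.gene_ids[i] for i in index],
        )


@dataclass
class LabelVector:
    """Per-cell cluster assignments, aligned with an :class:`ExpressionMatrix`.

    Each label is a cluster name or one of the sentinels ``Singleton``
    (dropped during splitting) and ``Unclassified`` (singleton too far from
    every cluster).
    """

    labels: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.labels) != len(self.cell_ids):
            raise ValueError("labels and cell_ids differ in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelVector):
            return NotImplemented
        return self.labels == other.labels and self.cell_ids == other.cell_ids

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def cluster_names(self) -> list[str]:
        """Distinct non-sentinel cluster names, in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            if lab not in SENTINELS:
                seen.setdefault(lab, None)
        return list(seen)
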