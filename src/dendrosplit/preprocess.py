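"""Preprocessing: zero-gene removal, cell count filtering, highly-variable
gene selection by binned dispersion, and the log10(x+1) transform.

The gene filter follows the binned-dispersion recipe common in droplet
scRNA-seq pipelines: genes are ranked by mean expression into equal-count
bins, dispersions (variance / mean) are z-scored within each bin, and only
genes above the z cutoff survive. It runs on raw (pre-log) values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .containers import ExpressionMatrix


@dataclass(frozen=True)
class GeneFilterParams:
    """Binned-dispersion gene filter settings (defaults: 5 bins, z > 1.5)."""

    num_bins: int = 5
    z_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if self.num_bins < 1:
            raise ValueError("num_bins must be >= 1")


@dataclass(frozen=True)
class CellFilterParams:
    """Cell total-count filter; cells with total counts strictly below
    ``min_total_count`` are removed (0 disables)."""

    min_total_count: float = 0.0

    def __post_init__(self) -> None:
        if self.min_total_count < 0:
            raise ValueError("min_total_count must be >= 0")


def log_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every entry x by log10(x + 1) and set the transform flag."""
    if X.log_transformed:
        raise ValueError("matrix is already log-transformed")
    if X.values.size and X.values.min() < 0:
        raise ValueError("log transform requires non-negative entries")
    return replace(X, values=np.log10(X.values + 1.0), log_transformed=True)


def drop_zero_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero expression across all cells, preserving order."""
    keep = np.any(X.values != 0, axis=0)
    if not keep.any():
        raise ValueError("all genes have zero expression across all cells")
    if keep.all():
        return X
    return X.subset_genes(keep)


def filter_cells_by_count(
    X: ExpressionMatrix, params: CellFilterParams
) -> ExpressionMatrix:
    """Keep cells whose total count is at least ``min_total_count``.

    Removal is strict ("less than"), so a cell exactly at the threshold
    survives. Operates on raw counts.
    """
    if X.log_transformed:
        raise ValueError("cell count filtering operates on raw counts")
    keep = X.values.sum(axis=1) >= params.min_total_count
    if not keep.any():
        raise ValueError("no cells pass the total-count filter")
    if keep.all():
        return X
    return X.subset_cells(keep)


def dispersion_gene_filter(
    X: ExpressionMatrix, params: GeneFilterParams
) -> ExpressionMatrix:
    """Keep highly-variable genes by within-bin z-scored dispersion.

    For each gene, dispersion = population variance / mean of the raw
    values. Genes are ranked by mean and split into ``num_bins``
    equal-count contiguous bins (ties in mean broken by column order);
    within each bin dispersions are z-normalised and genes with
    z > ``z_cutoff`` are kept, in their original column order. A bin with
    a single gene or zero dispersion spread contributes nothing (its
    z-scores are undefined) and triggers a warning.
    """
    if X.log_transformed:
        raise ValueError("dispersion filter operates on raw (pre-log) values")
    m = X.n_genes
    if params.num_bins > m:
        raise ValueError("num_bins exceeds the number of genes")
    means = X.values.mean(axis=0)
    if np.any(means == 0):
        raise ValueError("zero-mean genes present; apply drop_zero_genes first")
    variances = X.values.var(axis=0, ddof=0)
    dispersion = variances / means

    order = np.argsort(means, kind="stable")  # rank by mean, ties by column order
    bin_of_rank = (np.arange(m) * params.num_bins) // m
    bin_id = np.empty(m, dtype=int)
    bin_id[order] = bin_of_rank

    keep = np.zeros(m, dtype=bool)
    for b in range(params.num_bins):
        members = np.flatnonzero(bin_id == b)
        disp = dispersion[members]
        sd = disp.std(ddof=0)
        if members.size < 2 or sd == 0:
            warnings.warn(
                f"dispersion bin {b} has no spread; no genes selected from it",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        z = (disp - disp.mean()) / sd
        keep[members[z > params.z_cutoff]] = True

    if not keep.any():
        raise ValueError("no genes pass the dispersion filter")
    return X.subset_genes(keep)


def preprocess_pipeline(
    X_raw: ExpressionMatrix,
    cell_params: CellFilterParams | None = None,
    gene_params: GeneFilterParams | None = None,
) -> ExpressionMatrix:
    """The full preprocessing chain on a raw count/TPM matrix.

    Order: drop all-zero genes, filter low-count cells, drop genes zeroed
    by the cell filter, optionally apply the dispersion gene filter, then
    log10(x+1).
    """
    X = drop_zero_genes(X_raw)
    if cell_params is not None and cell_params.min_total_count > 0:
        X = filter_cells_by_count(X, cell_params)
        X = drop_zero_genes(X)
    if gene_params is not None:
        X = dispersion_gene_filter(X, gene_params)
    return log_transform(X)
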