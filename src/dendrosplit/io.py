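"""Readers and writers for expression matrices, distance matrices, label
vectors and split/merge histories.

Dense matrices travel as CSV/TSV with a header row of gene ids and a first
column of cell ids (rows = cells). Sparse matrices use the 10x-style
Matrix Market triple — ``matrix.mtx`` stored genes x cells with companion
``genes.tsv`` and ``barcodes.tsv`` — and are transposed to the in-memory
cells x genes convention on read. All round trips are lossless at full
float precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionMatrix, LabelVector
from .distance import DistanceMatrix
from .merge import MergeRecord
from .split import SplitHistory

_FORMATS = ("csv", "tsv", "mtx")


def dedupe_gene_ids(gene_ids: list[str]) -> list[str]:
    """Suffix duplicate gene symbols ".1", ".2", ... preserving order."""
    seen: dict[str, int] = {}
    out = []
    for g in gene_ids:
        if g in seen:
            seen[g] += 1
            out.append(f"{g}.{seen[g]}")
        else:
            seen[g] = 0
            out.append(g)
    return out


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".mtx":
        return "mtx"
    raise ValueError(f"cannot infer matrix format from {path.name!r}")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix, returning it oriented cells x genes.

    ``format`` is one of "csv", "tsv" or "mtx" (inferred from the file
    suffix when omitted). For "mtx", ``path`` is the ``.mtx`` file and
    ``genes.tsv``/``barcodes.tsv`` must sit beside it; the on-disk genes x
    cells orientation is transposed. Duplicate gene ids are suffixed.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "mtx":
        return _read_mtx_triple(path)
    sep = "," if fmt == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric entry at row {row!r}, column {col!r}")
    return ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=[str(c) for c in df.index],
        gene_ids=dedupe_gene_ids([str(g) for g in df.columns]),
    )


def _read_mtx_triple(mtx_path: Path) -> ExpressionMatrix:
    genes_path = mtx_path.parent / "genes.tsv"
    barcodes_path = mtx_path.parent / "barcodes.tsv"
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(f"missing companion file {p}")
    mat = spio.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    gene_ids = [str(g) for g in genes.iloc[:, 0]]
    cell_ids = [str(b) for b in barcodes.iloc[:, 0]]
    n_genes, n_cells = mat.shape
    if n_genes != len(gene_ids) or n_cells != len(cell_ids):
        raise ValueError(
            f"MTX header is {n_genes} genes x {n_cells} cells but companion "
            f"files list {len(gene_ids)} genes and {len(cell_ids)} barcodes"
        )
    dense = np.asarray(
        mat.todense() if sparse.issparse(mat) else mat, dtype=float
    ).T  # 10x stores genes x cells; in-memory convention is cells x genes
    return ExpressionMatrix(
        values=dense, cell_ids=cell_ids, gene_ids=dedupe_gene_ids(gene_ids)
    )


def write_expression(X: ExpressionMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a dense matrix as CSV/TSV, rows = cells, columns = genes."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "mtx":
        raise ValueError("writing the MTX triple is not supported; use csv/tsv")
    sep = "," if fmt == "csv" else "\t"
    df = pd.DataFrame(X.values, index=X.cell_ids, columns=X.gene_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_labels(path: str | Path) -> LabelVector:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LabelVector(
        labels=list(df.iloc[:, 1]) if len(df) else [],
        cell_ids=list(df.iloc[:, 0]) if len(df) else [],
    )


def write_labels(labels: LabelVector, path: str | Path) -> None:
    """Two-column TSV (cell_id, label); sentinels written literally."""
    df = pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels})
    df.to_csv(path, sep="\t", index=False)


def read_distance(path: str | Path) -> DistanceMatrix:
    """Square CSV with cell ids on both axes; invariants validated."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix row and column ids disagree")
    return DistanceMatrix(
        values=df.to_numpy(dtype=float),
        cell_ids=[str(c) for c in df.index],
        metric_name="precomputed",
    )


def write_distance(D: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(D.values, index=D.cell_ids, columns=D.cell_ids).to_csv(
        path, float_format="%.17g"
    )


def _encode(obj: Any) -> Any:
    """Recursively replace non-finite floats by the strings "inf"/"-inf"/"nan"
    so the history JSON stays standard-compliant."""
    if isinstance(obj, float):
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        if math.isnan(obj):
            return "nan"
        return obj
    if isinstance(obj, dict):
        return {k: _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, str) and obj in ("inf", "-inf", "nan"):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_history(
    history: SplitHistory,
    path: str | Path,
    merge_records: list[MergeRecord] | None = None,
    config: dict[str, Any] | None = None,
) -> None:
    """Serialise a split history (plus optional merge records and the run
    configuration) as JSON; infinite scores become the string "inf"."""
    payload = {
        "split_history": history.to_dict(),
        "merge_records": [r.to_dict() for r in (merge_records or [])],
        "config": config or {},
    }
    Path(path).write_text(json.dumps(_encode(payload), indent=1))


def read_history(path: str | Path) -> tuple[SplitHistory, list[MergeRecord], dict[str, Any]]:
    payload = _decode(json.loads(Path(path).read_text()))
    history = SplitHistory.from_dict(payload["split_history"])
    merges = [MergeRecord.from_dict(r) for r in payload.get("merge_records", [])]
    return history, merges, payload.get("config", {})
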