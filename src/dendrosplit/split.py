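"""Dendrogram construction and the recursive split step.

A complete-linkage dendrogram is built from the distance matrix (the
distance between two clusters is the largest pairwise distance between
their members). Splitting walks the tree from the root: a candidate split
is accepted when the separation score between the two child populations
exceeds the split threshold; an undersized child is disbanded into
singletons and the walk continues in the other child; a rejected or
terminal node becomes a candidate final cluster, which is itself disbanded
when all of its internal pairwise distances exceed a global distance
percentile (a cluster of mutual outliers).

Every decision is recorded in a :class:`SplitHistory` rich enough to (a)
explain each split via its most significant genes and (b) replay the
clustering for any larger threshold without re-running the tests (see
:mod:`dendrosplit.sweep`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import SINGLETON, ExpressionMatrix, LabelVector
from .distance import DistanceMatrix, distance_percentile
from .separation import separation_score, top_genes

logger = logging.getLogger(__name__)

# Split record decisions
ACCEPTED = "ACCEPTED"
REJECTED_SCORE = "REJECTED_SCORE"
SMALL_SIDE_DISBANDED = "SMALL_SIDE_DISBANDED"
DISBANDED_PERCENTILE = "DISBANDED_PERCENTILE"
LEAF_STOP = "LEAF_STOP"


@dataclass
class Dendrogram:
    """Binary agglomerative tree over N cells.

    Node ids follow the scipy convention: leaves are 0..N-1; internal node
    ``N + i`` joins ``children[i]`` at ``heights[i]``. The root is node
    ``2N - 2``.
    """

    n_leaves: int
    children: np.ndarray  # (N-1, 2) int: child node ids per merge
    heights: np.ndarray  # (N-1,) float: merge heights, non-decreasing

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def is_leaf(self, node: int) -> bool:
        return node < self.n_leaves

    def children_of(self, node: int) -> tuple[int, int]:
        i = node - self.n_leaves
        return int(self.children[i, 0]), int(self.children[i, 1])

    def leaves_of(self, node: int) -> np.ndarray:
        """Leaf (cell) indices under a node, in left-to-right tree order."""
        if self.is_leaf(node):
            return np.array([node], dtype=int)
        out: list[int] = []
        stack = [node]
        while stack:
            cur = stack.pop()
            if self.is_leaf(cur):
                out.append(cur)
            else:
                left, right = self.children_of(cur)
                stack.append(right)
                stack.append(left)
        return np.array(out, dtype=int)


def build_dendrogram(D: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative tree from a distance matrix (complete linkage).

    Deterministic given D; scipy breaks exact ties by smallest cluster
    index.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    if not np.all(np.isfinite(D.values)):
        raise ValueError("distance matrix entries must be finite")
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="complete")
    return Dendrogram(
        n_leaves=D.n_cells,
        children=Z[:, :2].astype(int),
        heights=Z[:, 2].astype(float),
    )


@dataclass(frozen=True)
class SplitParams:
    """Split-step hyperparameters.

    ``split_threshold`` gates split acceptance (strictly above accepts);
    ``min_cluster_size`` (>= 2) is the smallest population a side may have
    and still be scored; ``disband_percentile`` sets the global distance
    percentile against which candidate final clusters are checked for
    being pure outliers.
    """

    split_threshold: float = 20.0
    min_cluster_size: int = 2
    disband_percentile: float = 50.0

    def __post_init__(self) -> None:
        if not self.split_threshold > 0:
            raise ValueError("split_threshold must be > 0")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not 0 <= self.disband_percentile <= 100:
            raise ValueError("disband_percentile must lie in [0, 100]")


@dataclass
class SplitRecord:
    """One traversal step: the candidate split at a dendrogram node.

    ``score`` is None when the node was never scored (a side below the
    minimum cluster size, or a terminal stop). ``decision`` records the
    outcome; for final clusters that failed the outlier check it is
    ``DISBANDED_PERCENTILE`` and ``score`` tells whether a rejected score
    (not None) or a size stop (None) produced the candidate.
    """

    node_id: int
    name: str
    member_cells: list[str]
    left_cells: list[str]
    right_cells: list[str]
    left_node: int | None
    right_node: int | None
    score: float | None
    decision: str
    genes: list[tuple[str, float, float]] = field(default_factory=list)
    p_value_log10: list[float] | None = None  # full per-gene vector, opt-in

    def to_dict(self) -> dict[str, Any]:
        return {
            "node_id": self.node_id,
            "name": self.name,
            "member_cells": self.member_cells,
            "left_cells": self.left_cells,
            "right_cells": self.right_cells,
            "left_node": self.left_node,
            "right_node": self.right_node,
            "score": self.score,
            "decision": self.decision,
            "genes": [list(g) for g in self.genes],
            "p_value_log10": self.p_value_log10,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SplitRecord":
        return cls(
            node_id=int(d["node_id"]),
            name=d["name"],
            member_cells=list(d["member_cells"]),
            left_cells=list(d["left_cells"]),
            right_cells=list(d["right_cells"]),
            left_node=None if d["left_node"] is None else int(d["left_node"]),
            right_node=None if d["right_node"] is None else int(d["right_node"]),
            score=None if d["score"] is None else float(d["score"]),
            decision=d["decision"],
            genes=[(g[0], float(g[1]), float(g[2])) for g in d.get("genes", [])],
            p_value_log10=d.get("p_value_log10"),
        )


@dataclass
class SplitHistory:
    """Ordered record of the whole split traversal.

    Sufficient to regenerate split-step labels for any threshold at or
    above ``params.split_threshold`` (the scores of all accepted and
    rejected candidates are stored, and disband decisions are re-derived
    from the stored percentile cutoff).
    """

    records: list[SplitRecord]
    params: SplitParams
    percentile_cutoff: float
    cell_ids: list[str]

    def record_index(self) -> dict[int, SplitRecord]:
        return {r.node_id: r for r in self.records}

    def to_dict(self) -> dict[str, Any]:
        return {
            "records": [r.to_dict() for r in self.records],
            "params": {
                "split_threshold": self.params.split_threshold,
                "min_cluster_size": self.params.min_cluster_size,
                "disband_percentile": self.params.disband_percentile,
            },
            "percentile_cutoff": self.percentile_cutoff,
            "cell_ids": self.cell_ids,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SplitHistory":
        return cls(
            records=[SplitRecord.from_dict(r) for r in d["records"]],
            params=SplitParams(**d["params"]),
            percentile_cutoff=float(d["percentile_cutoff"]),
            cell_ids=list(d["cell_ids"]),
        )


def all_pairs_exceed(D_sub: np.ndarray, cutoff: float) -> bool:
    """True when every off-diagonal entry of a cluster's internal distance
    submatrix exceeds the cutoff (vacuously true for a single cell)."""
    n = D_sub.shape[0]
    if n < 2:
        return True
    iu = np.triu_indices(n, k=1)
    return bool(np.all(D_sub[iu] > cutoff))


def run_split(
    tree: Dendrogram,
    X: ExpressionMatrix,
    D: DistanceMatrix,
    params: SplitParams,
    top_k: int = 10,
    store_full_pvalues: bool = False,
) -> tuple[LabelVector, SplitHistory]:
    """Recursive split step: depth-first from the root, left child first.

    Cluster names encode the dendrogram position: the root is "r" and each
    accepted (or skipped-into) descent appends "L" or "R", so "rRL" is the
    left child of the right child of the root.

    Returns per-cell labels (cluster names or ``Singleton``) and the full
    :class:`SplitHistory`.
    """
    n = tree.n_leaves
    if X.n_cells != n or D.n_cells != n:
        raise ValueError("tree, expression matrix and distance matrix disagree in size")
    if X.cell_ids != D.cell_ids:
        raise ValueError("expression and distance matrices list different cells")

    cutoff = distance_percentile(D, params.disband_percentile)
    labels = np.empty(n, dtype=object)
    records: list[SplitRecord] = []
    cell_ids = X.cell_ids

    def names_of(idx: np.ndarray) -> list[str]:
        return [cell_ids[i] for i in idx]

    def finalize(members: np.ndarray, name: str, rec: SplitRecord) -> None:
        """Apply the outlier disband check to a candidate final cluster."""
        if all_pairs_exceed(D.submatrix(members), cutoff):
            rec.decision = DISBANDED_PERCENTILE
            labels[members] = SINGLETON
            logger.info(
                "cluster %s (%d cells) disbanded: all internal distances "
                "exceed the %.0fth-percentile cutoff %.4g",
                name, members.size, params.disband_percentile, cutoff,
            )
        else:
            labels[members] = name
        records.append(rec)

    stack: list[tuple[int, str]] = [(tree.root, "r")]
    while stack:
        node, name = stack.pop()
        members = tree.leaves_of(node)
        if tree.is_leaf(node):
            rec = SplitRecord(
                node_id=node, name=name, member_cells=names_of(members),
                left_cells=[], right_cells=[], left_node=None, right_node=None,
                score=None, decision=LEAF_STOP,
            )
            finalize(members, name, rec)
            continue

        left_node, right_node = tree.children_of(node)
        left = tree.leaves_of(left_node)
        right = tree.leaves_of(right_node)
        left_ok = left.size >= params.min_cluster_size
        right_ok = right.size >= params.min_cluster_size
        rec = SplitRecord(
            node_id=node, name=name, member_cells=names_of(members),
            left_cells=names_of(left), right_cells=names_of(right),
            left_node=left_node, right_node=right_node,
            score=None, decision=LEAF_STOP,
        )

        if left_ok and right_ok:
            result = separation_score(X.values[left], X.values[right])
            rec.score = result.score
            rec.genes = top_genes(result, top_k, X.gene_ids)
            if store_full_pvalues:
                rec.p_value_log10 = [float(v) for v in result.p_value_log10]
            if result.score > params.split_threshold:
                rec.decision = ACCEPTED
                records.append(rec)
                logger.info(
                    "split %s accepted: score %.3g (best gene %s), "
                    "%d | %d cells",
                    name, result.score, rec.genes[0][0], left.size, right.size,
                )
                # left child processed first
                stack.append((right_node, name + "R"))
                stack.append((left_node, name + "L"))
            else:
                rec.decision = REJECTED_SCORE
                finalize(members, name, rec)
        elif left_ok or right_ok:
            # one undersized side: disband it to singletons, continue on
            # the other candidate without scoring this level
            small, survivor, letter = (
                (right, left_node, "L") if left_ok else (left, right_node, "R")
            )
            rec.decision = SMALL_SIDE_DISBANDED
            labels[small] = SINGLETON
            records.append(rec)
            stack.append((survivor, name + letter))
        else:
            finalize(members, name, rec)

    history = SplitHistory(
        records=records, params=params, percentile_cutoff=cutoff,
        cell_ids=list(cell_ids),
    )
    return LabelVector(labels=list(labels), cell_ids=list(cell_ids)), history
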