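"""Post-split cleanup: singleton reassignment and iterative cluster merging.

Splitting is greedy, so related cells can end up in different subtrees and
lone cells can be stranded as singletons. Cleanup first gives each
singleton the cluster of its nearest clustered neighbour (unless that
neighbour is farther than a high percentile of all pairwise distances, in
which case the cell stays unclassified), then repeatedly merges the two
least-separated clusters while their separation score falls below the
merge threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np

from .containers import SENTINELS, SINGLETON, UNCLASSIFIED, ExpressionMatrix, LabelVector
from .distance import DistanceMatrix, distance_percentile
from .separation import separation_score, top_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParams:
    """Merge-step hyperparameters: the score threshold below which the two
    closest clusters merge, and the distance percentile beyond which a
    singleton's nearest neighbour is too far to adopt it."""

    merge_threshold: float = 10.0
    singleton_percentile: float = 90.0

    def __post_init__(self) -> None:
        if self.merge_threshold < 0:
            raise ValueError("merge_threshold must be >= 0")
        if not 0 <= self.singleton_percentile <= 100:
            raise ValueError("singleton_percentile must lie in [0, 100]")


@dataclass
class MergeRecord:
    """One executed merge: the pair, its separation score, and the genes
    that least failed to distinguish them."""

    cluster_a: str
    cluster_b: str
    score: float
    result_name: str
    genes: list[tuple[str, float, float]]

    @property
    def best_gene(self) -> str:
        return self.genes[0][0] if self.genes else ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "cluster_a": self.cluster_a,
            "cluster_b": self.cluster_b,
            "score": self.score,
            "result_name": self.result_name,
            "genes": [list(g) for g in self.genes],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MergeRecord":
        return cls(
            cluster_a=d["cluster_a"],
            cluster_b=d["cluster_b"],
            score=float(d["score"]),
            result_name=d["result_name"],
            genes=[(g[0], float(g[1]), float(g[2])) for g in d.get("genes", [])],
        )


def reassign_singletons(
    labels: LabelVector, D: DistanceMatrix, params: MergeParams
) -> LabelVector:
    """Attach each singleton to the cluster of its nearest clustered cell.

    Only cells holding a cluster label before this pass count as
    neighbours (a singleton never chains onto another singleton's fresh
    assignment). A singleton whose nearest clustered neighbour lies beyond
    the ``singleton_percentile`` of all pairwise distances becomes
    ``Unclassified``.
    """
    if labels.cell_ids != D.cell_ids:
        raise ValueError("labels and distance matrix list different cells")
    out = list(labels.labels)
    singles = [i for i, lab in enumerate(labels.labels) if lab == SINGLETON]
    if not singles:
        return LabelVector(labels=out, cell_ids=list(labels.cell_ids))
    clustered = np.array(
        [i for i, lab in enumerate(labels.labels) if lab not in SENTINELS], dtype=int
    )
    if clustered.size == 0:
        warnings.warn(
            "no clustered cells to reassign singletons to; all become unclassified",
            RuntimeWarning,
            stacklevel=2,
        )
        for i in singles:
            out[i] = UNCLASSIFIED
        return LabelVector(labels=out, cell_ids=list(labels.cell_ids))

    cutoff = distance_percentile(D, params.singleton_percentile)
    for i in singles:
        dists = D.values[i, clustered]
        j = int(np.argmin(dists))
        if dists[j] <= cutoff:
            out[i] = labels.labels[clustered[j]]
        else:
            out[i] = UNCLASSIFIED
    return LabelVector(labels=out, cell_ids=list(labels.cell_ids))


def _pair_stats(
    X: ExpressionMatrix, members: dict[str, np.ndarray], a: str, b: str, top_k: int
) -> tuple[float, float, list[tuple[str, float, float]]]:
    res = separation_score(X.values[members[a]], X.values[members[b]])
    genes = top_genes(res, top_k, X.gene_ids)
    best_abs_t = abs(genes[0][2])
    return res.score, best_abs_t, genes


def pairwise_separation_scores(
    labels: LabelVector, X: ExpressionMatrix, top_k: int = 1
) -> list[tuple[str, str, float, list[tuple[str, float, float]]]]:
    """Separation score for every unordered cluster pair, sorted ascending.

    The low end of this table is the principled way to choose a merge
    threshold: pairs below it will merge. Sentinel-labeled cells are
    ignored.
    """
    if labels.cell_ids != X.cell_ids:
        raise ValueError("labels and expression matrix list different cells")
    members = {
        name: np.array([i for i, lab in enumerate(labels.labels) if lab == name])
        for name in labels.cluster_names()
    }
    names = sorted(members)
    out = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            score, _, genes = _pair_stats(X, members, a, b, top_k)
            out.append((a, b, score, genes))
    out.sort(key=lambda row: (row[2], row[0], row[1]))
    return out


def merge_clusters(
    labels: LabelVector,
    X: ExpressionMatrix,
    params: MergeParams,
    top_k: int = 10,
) -> tuple[LabelVector, list[MergeRecord]]:
    """Iteratively merge the two least-separated clusters.

    Each round scores every unordered cluster pair with the separation
    score; the pair with the smallest score merges if that score is
    strictly below ``merge_threshold`` (ties broken by the smaller |t| of
    the best gene, then lexicographic pair names). Only pairs touching the
    merged cluster are rescored. Terminates when the minimum pairwise
    score reaches the threshold or a single cluster remains; on
    termination every surviving pair is separated by at least the
    threshold. Unclassified cells are untouched. Final clusters are
    renamed to consecutive integers by decreasing size.
    """
    if labels.cell_ids != X.cell_ids:
        raise ValueError("labels and expression matrix list different cells")
    members: dict[str, np.ndarray] = {}
    for name in labels.cluster_names():
        idx = np.array([i for i, lab in enumerate(labels.labels) if lab == name])
        if idx.size < 2:
            raise ValueError(f"cluster {name!r} has fewer than 2 members")
        members[name] = idx

    records: list[MergeRecord] = []
    if len(members) >= 2:
        cache: dict[tuple[str, str], tuple[float, float, list]] = {}

        def key(a: str, b: str) -> tuple[str, str]:
            return (a, b) if a < b else (b, a)

        names = sorted(members)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                cache[(a, b)] = _pair_stats(X, members, a, b, top_k)

        while len(members) > 1:
            # pick min score; ties by smaller best-gene |t|, then pair names
            (a, b), (score, _, genes) = min(
                cache.items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0])
            )
            if not score < params.merge_threshold:
                break
            members[a] = np.sort(np.concatenate([members[a], members.pop(b)]))
            records.append(
                MergeRecord(cluster_a=a, cluster_b=b, score=score,
                            result_name=a, genes=genes)
            )
            logger.info(
                "merged %s into %s: score %.3g (best gene %s)", b, a, score,
                genes[0][0] if genes else "-",
            )
            cache = {k: v for k, v in cache.items() if a not in k and b not in k}
            for other in members:
                if other != a:
                    cache[key(a, other)] = _pair_stats(X, members, a, other, top_k)

    # rename clusters to consecutive integers by decreasing size
    order = sorted(members, key=lambda name: (-members[name].size, name))
    rename = {old: str(i + 1) for i, old in enumerate(order)}
    out = list(labels.labels)
    for old, idx in members.items():
        for i in idx:
            out[i] = rename[old]
    for rec in records:
        rec.result_name = rename.get(rec.result_name, rec.result_name)
    return LabelVector(labels=out, cell_ids=list(labels.cell_ids)), records
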