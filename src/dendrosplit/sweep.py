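"""Threshold sweeping: regenerate split-step labels from a saved history.

Clusterings produced at a smaller split threshold partition those produced
at a larger one, so a history recorded at a small threshold already
contains the scores of every split a stricter run would consider. Replay
therefore walks the recorded traversal, accepting a stored split only when
its stored score clears the new threshold, and re-derives the candidate
final clusters' outlier (disband) checks against the stored percentile
cutoff. The result is identical, label for label, to a fresh run at the
new threshold — at the cost of a tree walk instead of thousands of
t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import SINGLETON, LabelVector
from .distance import DistanceMatrix
from .metrics import cluster_count
from .split import SMALL_SIDE_DISBANDED, SplitHistory, all_pairs_exceed


def resplit_from_history(
    history: SplitHistory, new_threshold: float, D: DistanceMatrix
) -> LabelVector:
    """Split-step labels at ``new_threshold``, replayed from a history.

    ``new_threshold`` must be at least the threshold the history was run
    with (records below that level were never explored). Matches a fresh
    :func:`dendrosplit.split.run_split` at the same threshold exactly.
    """
    if new_threshold < history.params.split_threshold:
        raise ValueError(
            f"new threshold {new_threshold} is below the history threshold "
            f"{history.params.split_threshold}; run the split step afresh"
        )
    if D.cell_ids != history.cell_ids:
        raise ValueError("distance matrix and history list different cells")

    index = history.record_index()
    cell_pos = {c: i for i, c in enumerate(history.cell_ids)}
    labels = np.empty(len(history.cell_ids), dtype=object)
    min_size = history.params.min_cluster_size
    cutoff = history.percentile_cutoff

    def finalize(members: list[str], name: str) -> None:
        idx = np.array([cell_pos[c] for c in members], dtype=int)
        if all_pairs_exceed(D.submatrix(idx), cutoff):
            labels[idx] = SINGLETON
        else:
            labels[idx] = name

    root = history.records[0]
    stack: list[tuple[int, str]] = [(root.node_id, root.name)]
    while stack:
        node, name = stack.pop()
        rec = index[node]
        if rec.decision == SMALL_SIDE_DISBANDED:
            left_small = len(rec.left_cells) < min_size
            small = rec.left_cells if left_small else rec.right_cells
            survivor = rec.right_node if left_small else rec.left_node
            letter = "R" if left_small else "L"
            idx = np.array([cell_pos[c] for c in small], dtype=int)
            labels[idx] = SINGLETON
            stack.append((survivor, name + letter))
        elif rec.score is not None and rec.score > new_threshold:
            # was accepted in the original run, hence children records exist
            stack.append((rec.right_node, name + "R"))
            stack.append((rec.left_node, name + "L"))
        else:
            finalize(rec.member_cells, name)

    return LabelVector(labels=list(labels), cell_ids=list(history.cell_ids))


@dataclass
class SweepEntry:
    threshold: float
    labels: LabelVector
    n_clusters: int


def sweep_thresholds(
    history: SplitHistory, thresholds: list[float], D: DistanceMatrix
) -> list[SweepEntry]:
    """Replay the split step at each threshold; report non-singleton
    cluster counts for an elbow-style summary."""
    out = []
    for t in thresholds:
        labels = resplit_from_history(history, t, D)
        out.append(
            SweepEntry(threshold=float(t), labels=labels,
                       n_clusters=cluster_count(labels, include_sentinels=False))
        )
    return out
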