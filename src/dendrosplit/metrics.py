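"""Clustering evaluation: the adjusted Rand index and cluster counting.

The ARI is the pair-counting Rand index corrected for chance
(Hubert-Arabie): with contingency counts n_ij between partitions X and Y,
row sums a_i, column sums b_j and n elements,

    ARI = [sum_ij C(n_ij,2) - E] / [ (sum_i C(a_i,2) + sum_j C(b_j,2))/2 - E ]

where E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2). Identical partitions
score 1; independent random labelings score ~0.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import SENTINELS, LabelVector


def _expand_sentinels(labels: list[str]) -> list[str]:
    """Give each sentinel-labeled cell its own singleton class."""
    return [
        f"{lab}#{i}" if lab in SENTINELS else lab for i, lab in enumerate(labels)
    ]


def contingency_table(
    labels_x: list[str], labels_y: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts n_ij of elements shared by class i of X and class j of Y,
    with row sums a_i and column sums b_j."""
    xs = sorted(set(labels_x))
    ys = sorted(set(labels_y))
    xi = {c: i for i, c in enumerate(xs)}
    yi = {c: i for i, c in enumerate(ys)}
    n = np.zeros((len(xs), len(ys)), dtype=np.int64)
    for a, b in zip(labels_x, labels_y):
        n[xi[a], yi[b]] += 1
    return n, n.sum(axis=1), n.sum(axis=0)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2


def adjusted_rand_index(
    labels_x: LabelVector | list[str],
    labels_y: LabelVector | list[str],
    exclude_sentinels: bool = False,
) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    Sentinel-labeled cells (``Singleton``/``Unclassified``) each form
    their own one-element class by default, counting as unmatched;
    ``exclude_sentinels`` drops any cell carrying a sentinel in either
    labeling instead. In the degenerate case where the adjustment
    denominator is zero (e.g. both partitions are a single class), the
    index is 1 for identical partitions and 0 otherwise.
    """
    lx = list(labels_x.labels if isinstance(labels_x, LabelVector) else labels_x)
    ly = list(labels_y.labels if isinstance(labels_y, LabelVector) else labels_y)
    if len(lx) != len(ly):
        raise ValueError("label vectors differ in length")
    if exclude_sentinels:
        keep = [i for i in range(len(lx)) if lx[i] not in SENTINELS and ly[i] not in SENTINELS]
        lx = [lx[i] for i in keep]
        ly = [ly[i] for i in keep]
    else:
        lx = _expand_sentinels(lx)
        ly = _expand_sentinels(ly)
    n_elems = len(lx)
    if n_elems < 2:
        raise ValueError("need at least 2 elements to compare partitions")

    nij, a, b = contingency_table(lx, ly)
    sum_ij = _comb2(nij).sum()
    sum_a = _comb2(a).sum()
    sum_b = _comb2(b).sum()
    expected = sum_a * sum_b / _comb2(np.array(n_elems))
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        # partitions are identical iff the contingency table is a
        # (scaled) permutation matrix: one nonzero per row and column
        identical = (nij != 0).sum() == len(a) == len(b)
        warnings.warn(
            "ARI denominator is zero (degenerate partitions); returning "
            "1 for identical partitions, 0 otherwise",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / denom)


def cluster_count(
    labels: LabelVector | list[str], include_sentinels: bool = False
) -> int:
    """Number of distinct cluster names; sentinels optionally count as one
    class each."""
    labs = list(labels.labels if isinstance(labels, LabelVector) else labels)
    names = {lab for lab in labs if lab not in SENTINELS}
    if include_sentinels:
        names |= {lab for lab in labs if lab in SENTINELS}
    return len(names)
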