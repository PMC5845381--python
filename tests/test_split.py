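"""Dendrogram construction and the recursive split step."""

import numpy as np
import pytest

from dendrosplit import (
    DistanceMatrix,
    ExpressionMatrix,
    SINGLETON,
    SplitParams,
    build_dendrogram,
    distance_matrix,
    make_blobs_2d,
    points_to_expression,
    run_split,
)
from dendrosplit.split import ACCEPTED, DISBANDED_PERCENTILE


def dist_from_upper(n, entries):
    v = np.zeros((n, n))
    v[np.triu_indices(n, 1)] = entries
    return DistanceMatrix(values=v + v.T, cell_ids=[f"c{i}" for i in range(n)],
                          metric_name="precomputed")


class TestBuildDendrogram:
    def test_two_leaves(self):
        D = dist_from_upper(2, [0.7])
        tree = build_dendrogram(D)
        assert tree.root == 2
        assert set(tree.children_of(2)) == {0, 1}
        assert tree.heights[0] == pytest.approx(0.7)

    def test_three_point_hand_trace(self):
        # d(0,1)=1, d(0,2)=2, d(1,2)=3: first merge {0,1} at 1, then the
        # root joins leaf 2 at complete-linkage height max(2,3)=3
        D = dist_from_upper(3, [1.0, 2.0, 3.0])
        tree = build_dendrogram(D)
        first_children = set(tree.children_of(3))
        assert first_children == {0, 1}
        assert tree.heights[0] == pytest.approx(1.0)
        assert tree.heights[1] == pytest.approx(3.0)

    def test_heights_non_decreasing(self, rng):
        for _ in range(5):
            n = 12
            v = rng.random((n, n))
            v = np.triu(v, 1)
            D = DistanceMatrix(values=v + v.T, metric_name="precomputed",
                               cell_ids=[f"c{i}" for i in range(n)])
            tree = build_dendrogram(D)
            assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_leaf_sets_partition(self, rng):
        n = 10
        v = np.triu(rng.random((n, n)), 1)
        D = DistanceMatrix(values=v + v.T, metric_name="precomputed",
                           cell_ids=[f"c{i}" for i in range(n)])
        tree = build_dendrogram(D)
        for node in range(n, 2 * n - 1):
            left, right = tree.children_of(node)
            lset = set(tree.leaves_of(left))
            rset = set(tree.leaves_of(right))
            assert lset.isdisjoint(rset)
            assert lset | rset == set(tree.leaves_of(node))


def blob_fixture(k=2, n=20, seed=0, separation=12.0):
    pts, truth = make_blobs_2d(k, n, separation=separation, seed=seed)
    X = points_to_expression(pts, cell_ids=truth.cell_ids)
    D = distance_matrix(X, metric="euclidean")
    return X, D, truth


class TestRunSplit:
    def test_infinite_threshold_single_cluster(self):
        X, D, _ = blob_fixture()
        tree = build_dendrogram(D)
        labels, history = run_split(tree, X, D, SplitParams(split_threshold=1e308))
        assert set(labels.labels) == {"r"}
        assert all(r.decision != ACCEPTED for r in history.records)

    def test_two_populations_split_at_root(self):
        """Two well-separated Gaussian blobs: exactly one accepted split at
        the root, recovering the planted populations."""
        X, D, truth = blob_fixture(k=2, n=20, seed=3)
        tree = build_dendrogram(D)
        labels, history = run_split(tree, X, D, SplitParams(split_threshold=10))
        accepted = [r for r in history.records if r.decision == ACCEPTED]
        assert len(accepted) == 1 and accepted[0].name == "r"
        assert accepted[0].score > 10
        groups = {}
        for lab, t in zip(labels.labels, truth.labels):
            if lab != SINGLETON:  # a stray singleton split-off is legitimate
                groups.setdefault(lab, set()).add(t)
        assert all(len(v) == 1 for v in groups.values())
        assert len(groups) == 2

    def test_four_blobs_recovered(self):
        """Four 2-D Gaussian blobs with Euclidean distance and split
        threshold 30 give four final clusters matching the components."""
        X, D, truth = blob_fixture(k=4, n=25, seed=1)
        tree = build_dendrogram(D)
        labels, _ = run_split(tree, X, D, SplitParams(split_threshold=30))
        from dendrosplit import adjusted_rand_index

        non_singleton = [l for l in labels.labels if l != SINGLETON]
        assert len(set(non_singleton)) == 4
        assert adjusted_rand_index(truth, labels, exclude_sentinels=True) == 1.0

    def test_partition_property(self):
        X, D, _ = blob_fixture(k=3, n=10, seed=5)
        tree = build_dendrogram(D)
        labels, _ = run_split(tree, X, D, SplitParams(split_threshold=5))
        assert len(labels) == X.n_cells  # every cell labeled or singleton
        assert all(lab for lab in labels.labels)

    def test_deterministic(self):
        X, D, _ = blob_fixture(k=3, n=12, seed=9)
        tree = build_dendrogram(D)
        out1 = run_split(tree, X, D, SplitParams(split_threshold=8))
        out2 = run_split(tree, X, D, SplitParams(split_threshold=8))
        assert out1[0] == out2[0]
        assert [r.to_dict() for r in out1[1].records] == [
            r.to_dict() for r in out2[1].records
        ]

    def test_accepted_scores_exceed_threshold(self):
        X, D, _ = blob_fixture(k=4, n=15, seed=2)
        tree = build_dendrogram(D)
        _, history = run_split(tree, X, D, SplitParams(split_threshold=12))
        for rec in history.records:
            if rec.decision == ACCEPTED:
                assert rec.score > 12

    def test_cluster_names_encode_tree_position(self):
        X, D, _ = blob_fixture(k=4, n=15, seed=2)
        tree = build_dendrogram(D)
        labels, history = run_split(tree, X, D, SplitParams(split_threshold=12))
        assert history.records[0].name == "r"
        for name in set(labels.labels) - {SINGLETON}:
            assert name[0] == "r" and set(name[1:]) <= {"L", "R"}

    def test_outlier_cluster_disbanded(self, rng):
        """A terminal pair of mutual outliers, farther apart than the
        median pairwise distance, is disbanded into singletons."""
        # two tight 4-cell clusters plus a loose far-away pair: the pair's
        # internal distance (30) exceeds the global median (~20, set by the
        # inter-cluster distances), so the pair fails the disband check
        jitter = 0.05 * rng.standard_normal((8, 2))
        tight = np.array([[0.0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1]])
        pts = np.vstack([
            tight + jitter[:4],
            tight + [20, 0] + jitter[4:],
            [[100.0, 100.0], [130.0, 100.0]],
        ])
        X = points_to_expression(pts)
        D = distance_matrix(X, metric="euclidean")
        tree = build_dendrogram(D)
        labels, history = run_split(tree, X, D, SplitParams(split_threshold=5))
        assert labels.labels[8] == SINGLETON
        assert labels.labels[9] == SINGLETON
        assert any(r.decision == DISBANDED_PERCENTILE for r in history.records)
        assert len(set(labels.labels) - {SINGLETON}) == 2

    def test_size_mismatch_raises(self):
        X, D, _ = blob_fixture()
        tree = build_dendrogram(D)
        bad = ExpressionMatrix(values=X.values[:-1], cell_ids=X.cell_ids[:-1],
                               gene_ids=X.gene_ids, log_transformed=True)
        with pytest.raises(ValueError):
            run_split(tree, bad, D, SplitParams())
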