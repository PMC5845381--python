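"""Singleton reassignment and the iterative merge step."""

import numpy as np
import pytest

from dendrosplit import (
    DistanceMatrix,
    ExpressionMatrix,
    LabelVector,
    MergeParams,
    SINGLETON,
    UNCLASSIFIED,
    merge_clusters,
    reassign_singletons,
    separation_score,
)


def dist(values, ids):
    return DistanceMatrix(values=np.asarray(values, float), cell_ids=ids,
                          metric_name="precomputed")


class TestReassignSingletons:
    def test_identity_without_singletons(self):
        ids = ["a", "b", "c"]
        labels = LabelVector(["x", "x", "y"], ids)
        D = dist(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]), ids)
        assert reassign_singletons(labels, D, MergeParams()) == labels

    def test_nearby_singleton_adopts_cluster(self):
        ids = ["a", "b", "c", "s"]
        labels = LabelVector(["A", "A", "B", SINGLETON], ids)
        v = np.array([
            [0.0, 0.2, 0.9, 0.1],
            [0.2, 0.0, 0.8, 0.3],
            [0.9, 0.8, 0.0, 0.7],
            [0.1, 0.3, 0.7, 0.0],
        ])
        out = reassign_singletons(labels, dist(v, ids), MergeParams())
        assert out.labels[3] == "A"

    def test_distant_singleton_unclassified(self):
        """A singleton beyond the 90th percentile of pairwise distances
        from every clustered cell stays unclassified."""
        n = 20  # big tight cluster so >90% of all pairs are short
        ids = [f"c{i}" for i in range(n)] + ["s"]
        labels = LabelVector(["A"] * n + [SINGLETON], ids)
        v = np.full((n + 1, n + 1), 0.1)
        v[n, :] = v[:, n] = 10.0  # singleton far from every clustered cell
        np.fill_diagonal(v, 0.0)
        out = reassign_singletons(labels, dist(v, ids), MergeParams())
        assert out.labels[n] == UNCLASSIFIED

    def test_no_clustered_cells_warns(self):
        ids = ["a", "b"]
        labels = LabelVector([SINGLETON, SINGLETON], ids)
        D = dist([[0, 1], [1, 0.0]], ids)
        with pytest.warns(RuntimeWarning):
            out = reassign_singletons(labels, D, MergeParams())
        assert out.labels == [UNCLASSIFIED, UNCLASSIFIED]

    def test_no_chaining_between_singletons(self):
        """A singleton is never assigned via another singleton's fresh
        label, only via cells clustered before the pass."""
        ids = ["a", "b", "s1", "s2"]
        labels = LabelVector(["A", "A", SINGLETON, SINGLETON], ids)
        # s2's nearest cell overall is s1; its nearest *clustered* cell is b
        v = np.array([
            [0.0, 0.1, 0.5, 0.9],
            [0.1, 0.0, 0.4, 0.8],
            [0.5, 0.4, 0.0, 0.05],
            [0.9, 0.8, 0.05, 0.0],
        ])
        out = reassign_singletons(labels, dist(v, ids), MergeParams())
        assert out.labels[2] == "A" and out.labels[3] == "A"


def planted_expression(rng, sizes, shifts, n_genes=20):
    """Clusters of Gaussian cells; cluster i's first gene mean is shifts[i]."""
    blocks = []
    for size, shift in zip(sizes, shifts):
        block = rng.normal(0, 1, (size, n_genes))
        block[:, 0] += shift
        blocks.append(block)
    values = np.vstack(blocks)
    ids = [f"c{i}" for i in range(values.shape[0])]
    X = ExpressionMatrix(values=values, cell_ids=ids,
                         gene_ids=[f"g{j}" for j in range(n_genes)],
                         log_transformed=True)
    labels = LabelVector(
        [f"k{i}" for i, s in enumerate(sizes) for _ in range(s)], ids
    )
    return X, labels


class TestMergeClusters:
    def test_well_separated_clusters_untouched(self, rng):
        X, labels = planted_expression(rng, [15, 15], [0, 10])
        out, records = merge_clusters(labels, X, MergeParams(merge_threshold=5))
        assert records == []
        assert len(set(out.labels)) == 2

    def test_same_distribution_clusters_merge(self, rng):
        """Two clusters drawn from one distribution merge; a shifted third
        survives with a threshold between the two score regimes."""
        X, labels = planted_expression(rng, [15, 15, 15], [0, 0, 12])
        out, records = merge_clusters(labels, X, MergeParams(merge_threshold=8))
        assert len(records) == 1
        assert {records[0].cluster_a, records[0].cluster_b} == {"k0", "k1"}
        assert len(set(out.labels)) == 2
        # renamed to consecutive integers by decreasing size
        assert set(out.labels) == {"1", "2"}
        sizes = {lab: out.labels.count(lab) for lab in set(out.labels)}
        assert sizes["1"] == 30 and sizes["2"] == 15

    def test_zero_threshold_never_merges(self, rng):
        X, labels = planted_expression(rng, [10, 10], [0, 0])
        out, records = merge_clusters(labels, X, MergeParams(merge_threshold=0))
        assert records == []

    def test_termination_contract(self, rng):
        """After termination every remaining pairwise separation score is
        at least the merge threshold."""
        X, labels = planted_expression(rng, [12, 12, 12, 12], [0, 0.5, 1.0, 9])
        thr = 4.0
        out, records = merge_clusters(labels, X, MergeParams(merge_threshold=thr))
        names = out.cluster_names()
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ia = [k for k, lab in enumerate(out.labels) if lab == a]
                ib = [k for k, lab in enumerate(out.labels) if lab == b]
                score = separation_score(X.values[ia], X.values[ib]).score
                assert score >= thr
        for rec in records:
            assert rec.score < thr

    def test_merge_count_bounded(self, rng):
        X, labels = planted_expression(rng, [10, 10, 10], [0, 0, 0])
        _, records = merge_clusters(labels, X, MergeParams(merge_threshold=1e6))
        assert len(records) == 2  # k initial clusters allow k-1 merges

    def test_unclassified_untouched(self, rng):
        X, labels = planted_expression(rng, [10, 10], [0, 10])
        labs = list(labels.labels)
        labs[0] = UNCLASSIFIED
        labels = LabelVector(labs, labels.cell_ids)
        out, _ = merge_clusters(labels, X, MergeParams(merge_threshold=1e6))
        assert out.labels[0] == UNCLASSIFIED

    def test_single_cluster_returned_unchanged(self, rng):
        X, labels = planted_expression(rng, [10], [0])
        out, records = merge_clusters(labels, X, MergeParams())
        assert records == [] and len(set(out.labels)) == 1


class TestPairwiseScores:
    def test_sorted_ascending_and_complete(self, rng):
        from dendrosplit import pairwise_separation_scores, separation_score

        X, labels = planted_expression(rng, [12, 12, 12], [0, 1, 10])
        table = pairwise_separation_scores(labels, X)
        assert len(table) == 3  # C(3,2) pairs
        scores = [row[2] for row in table]
        assert scores == sorted(scores)
        for a, b, score, _ in table:
            ia = [i for i, lab in enumerate(labels.labels) if lab == a]
            ib = [i for i, lab in enumerate(labels.labels) if lab == b]
            assert score == separation_score(X.values[ia], X.values[ib]).score
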