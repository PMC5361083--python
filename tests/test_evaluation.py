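"""Metric correctness: splits, confusion, P/R/F, weighted averages, MRR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import redthemes as rt
from redthemes.cohort import LabeledCorpus
from redthemes.evaluation import (
    ConfusionMatrix,
    ablate_class,
    binary_metrics,
    confusion,
    mean_reciprocal_rank,
    multiclass_metrics,
    rank_of_truth,
    split_dataset,
)

from conftest import make_post


def toy_corpus(labels):
    posts = [make_post(post_id=f"p{i}") for i in range(len(labels))]
    return LabeledCorpus(posts, list(labels))


class TestSplitDataset:
    def test_ten_posts_split_eight_two(self):
        train, test = split_dataset(toy_corpus(["a"] * 10), 0.8, seed=1)
        assert len(train) == 8 and len(test) == 2

    def test_same_seed_same_partition(self):
        c = toy_corpus(["a", "b"] * 20)
        t1 = split_dataset(c, 0.8, seed=3)
        t2 = split_dataset(c, 0.8, seed=3)
        assert [p.post_id for p in t1[0].posts] == [p.post_id for p in t2[0].posts]

    def test_partition_is_exact_and_disjoint(self):
        c = toy_corpus(["a"] * 37)
        train, test = split_dataset(c, 0.8, seed=0)
        ids = {p.post_id for p in train.posts} | {p.post_id for p in test.posts}
        assert len(ids) == 37 and len(train) + len(test) == 37

    def test_class_proportions_roughly_preserved(self):
        labels = ["a"] * 6000 + ["b"] * 4000
        train, test = split_dataset(toy_corpus(labels), 0.8, seed=2)
        frac = test.labels.count("a") / len(test)
        assert abs(frac - 0.6) < 0.03

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.7])
    def test_fraction_out_of_range_rejected(self, frac):
        with pytest.raises(ValueError):
            split_dataset(toy_corpus(["a", "b"]), frac, seed=0)


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert cm.counts.tolist() == [[2, 0], [0, 1]]

    def test_worked_two_class_example(self):
        cm = confusion(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_label_outside_order_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion(["a"], ["z"], ["a", "b"])

    def test_random_labels_match_brute_force_tally(self):
        rng = np.random.default_rng(7)
        classes = list("abcd")
        truth = rng.choice(classes, 1000)
        pred = rng.choice(classes, 1000)
        cm = confusion(truth, pred, classes)
        for i, t in enumerate(classes):
            for j, p in enumerate(classes):
                assert cm.counts[i, j] == sum(
                    1 for x, y in zip(truth, pred) if x == t and y == p
                )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.array([[1, -1], [0, 2]]), ("a", "b"))


class TestBinaryMetrics:
    def test_perfect_matrix(self):
        r = binary_metrics(ConfusionMatrix(np.diag([10, 10]), ("neg", "pos")))
        pos = r.per_class["pos"]
        assert (pos.precision, pos.recall, pos.f_measure, r.accuracy) == (1, 1, 1, 1)

    def test_everything_wrong_reports_zeros_with_warnings(self):
        r = binary_metrics(ConfusionMatrix(np.array([[0, 5], [5, 0]]), ("neg", "pos")))
        pos = r.per_class["pos"]
        assert pos.precision == 0 and pos.recall == 0 and r.accuracy == 0
        assert r.warnings  # F-measure denominator was zero

    def test_accuracy_equals_weighted_recall(self):
        cm = ConfusionMatrix(np.array([[30, 12], [7, 51]]), ("neg", "pos"))
        r = binary_metrics(cm)
        assert r.accuracy == pytest.approx(r.weighted_recall)


class TestMulticlassMetrics:
    def test_diagonal_matrix_is_perfect(self):
        r = multiclass_metrics(ConfusionMatrix(np.diag([3, 5, 9]), ("a", "b", "c")))
        assert r.accuracy == 1.0
        assert r.weighted_precision == r.weighted_recall == r.weighted_f_measure == 1.0

    def test_three_class_hand_computed_example(self):
        cm = ConfusionMatrix(
            np.array([[5, 1, 0], [0, 4, 2], [1, 0, 7]]), ("a", "b", "c")
        )
        r = multiclass_metrics(cm)
        assert r.per_class["a"].recall == pytest.approx(5 / 6)
        assert r.per_class["a"].precision == pytest.approx(5 / 6)
        assert r.per_class["b"].precision == pytest.approx(4 / 5)
        assert r.per_class["b"].recall == pytest.approx(4 / 6)
        assert r.per_class["c"].precision == pytest.approx(7 / 9)
        assert r.per_class["c"].recall == pytest.approx(7 / 8)
        assert r.accuracy == pytest.approx(16 / 20)
        assert r.weighted_recall == pytest.approx(r.accuracy)

    def test_class_permutation_leaves_weighted_averages_unchanged(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(4, 4))
        counts[np.diag_indices(4)] += 5
        base = multiclass_metrics(ConfusionMatrix(counts, tuple("abcd")))
        perm = [2, 0, 3, 1]
        permuted = multiclass_metrics(
            ConfusionMatrix(counts[np.ix_(perm, perm)],
                            tuple("abcd"[i] for i in perm))
        )
        assert permuted.weighted_precision == pytest.approx(base.weighted_precision)
        assert permuted.weighted_f_measure == pytest.approx(base.weighted_f_measure)
        assert permuted.accuracy == pytest.approx(base.accuracy)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            multiclass_metrics(ConfusionMatrix(np.zeros((3, 3), int), ("a", "b", "c")))

    def test_agrees_with_sklearn_on_random_predictions(self):
        # independent route: sklearn computes the same quantities from the
        # raw label vectors rather than from our confusion matrix
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(3)
        classes = list("abcde")
        truth = rng.choice(classes, 500)
        pred = rng.choice(classes, 500)
        r = multiclass_metrics(confusion(truth, pred, classes))
        p, rec, f, _ = precision_recall_fscore_support(
            truth, pred, labels=classes, average="weighted", zero_division=0
        )
        assert r.weighted_precision == pytest.approx(p, abs=1e-12)
        assert r.weighted_recall == pytest.approx(rec, abs=1e-12)
        assert r.weighted_f_measure == pytest.approx(f, abs=1e-12)


class TestMeanReciprocalRank:
    def test_all_true_classes_ranked_first(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2]])
        assert mean_reciprocal_rank(probs, [0, 0]) == 1.0

    def test_ranks_one_and_two_average(self):
        probs = np.array([[0.9, 0.1], [0.7, 0.3]])
        assert mean_reciprocal_rank(probs, [0, 1]) == pytest.approx(0.75)

    def test_probability_ties_broken_by_ascending_class_index(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        assert rank_of_truth(probs, [0])[0] == 1
        assert rank_of_truth(probs, [1])[0] == 2

    def test_truth_outside_ranking_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            mean_reciprocal_rank(np.array([[0.5, 0.5]]), [2])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 11), st.integers(5, 60))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mrr_at_least_accuracy(self, seed, k, n):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(k), size=n)
        truth = rng.integers(0, k, size=n)
        acc = float((probs.argmax(axis=1) == truth).mean())
        assert mean_reciprocal_rank(probs, truth) >= acc


class TestAblateClass:
    def test_removing_empty_class_is_identity(self):
        c = toy_corpus(["a", "b", "b"])
        out = ablate_class(c, "zzz")
        assert out.labels == c.labels and out.posts == c.posts

    def test_cannot_reduce_below_two_classes(self):
        with pytest.raises(ValueError):
            ablate_class(toy_corpus(["a"] * 10 + ["b"] * 5), "a")

    def test_removes_every_post_of_the_class(self):
        out = ablate_class(toy_corpus(["a", "b", "c", "a"]), "a")
        assert out.labels == ["b", "c"] and len(out.posts) == 2
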