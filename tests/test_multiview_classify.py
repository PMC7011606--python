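"""Split protocol, majority-vote fusion, and MI-SVM witness alternation."""

import math
from collections import Counter

import numpy as np
import pytest

from gearcri.multiview_classify import (
    ACTION_CLASSES,
    LinearModel,
    MultiViewActionInstance,
    bag_scores_mi,
    evaluate,
    make_splits,
    predict_mi,
    predict_mv,
    train_mi_svm,
    train_svm_mv,
    unroll_views,
)
from gearcri.synthetic_scene import make_feature_bags


def bags_from_counts(counts, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    bags = []
    for label, n in counts.items():
        for i in range(n):
            bags.append(
                MultiViewActionInstance(
                    f"{label}_{i}",
                    {v: rng.standard_normal(dim) for v in range(5)},
                    label,
                )
            )
    return bags


class TestMakeSplits:
    def test_protocol_counts_for_the_recorded_class_sizes(self):
        counts = {"crawling": 166, "sitting": 228, "standing": 406, "walking": 248}
        bags = bags_from_counts(counts)
        plan = make_splits(bags, n_splits=5, train_frac=0.8, seed=0)
        for train, test in plan.splits:
            assert len(train) == 840
            assert len(test) == 208
            assert 5 * len(train) == 4200  # per-view videos
            assert 5 * len(test) == 1040

    def test_exact_division_case(self):
        bags = bags_from_counts({"crawling": 10, "sitting": 10})
        plan = make_splits(bags, n_splits=2, train_frac=0.8, seed=1)
        for train, test in plan.splits:
            assert len(train) == 16 and len(test) == 4
            for label in ("crawling", "sitting"):
                assert sum(t.startswith(label) for t in train) == 8

    @pytest.mark.parametrize("seed", [0, 3])
    def test_split_integrity(self, seed):
        counts = {"crawling": 17, "sitting": 23, "standing": 41, "walking": 25}
        bags = bags_from_counts(counts)
        plan = make_splits(bags, n_splits=4, train_frac=0.8, seed=seed)
        all_ids = {b.instance_id for b in bags}
        for train, test in plan.splits:
            assert set(train) & set(test) == set()
            assert set(train) | set(test) == all_ids
            for label, n in counts.items():
                n_train = sum(t.startswith(label) for t in train)
                assert n_train == math.ceil(0.8 * n)

    def test_reproducible_from_seed(self):
        bags = bags_from_counts({"crawling": 9, "walking": 11})
        a = make_splits(bags, seed=5)
        b = make_splits(bags, seed=5)
        assert a.splits == b.splits

    def test_singleton_class_rejected(self):
        bags = bags_from_counts({"crawling": 5, "walking": 1})
        with pytest.raises(ValueError, match="walking"):
            make_splits(bags)


def separable_bags(n_per_class=8, dim=8, seed=0, identical_views=False):
    rng = np.random.default_rng(seed)
    means = {c: 6.0 * rng.standard_normal(dim) for c in ACTION_CLASSES}
    bags = []
    for c in ACTION_CLASSES:
        for i in range(n_per_class):
            if identical_views:
                x = means[c] + 0.3 * rng.standard_normal(dim)
                emb = {v: x.copy() for v in range(5)}
            else:
                emb = {
                    v: means[c] + 0.3 * rng.standard_normal(dim) for v in range(5)
                }
            bags.append(MultiViewActionInstance(f"{c}_{i}", emb, c))
    return bags


class TestSvmMv:
    def test_label_transfer_produces_one_row_per_view(self):
        bags = separable_bags(n_per_class=2)
        X, y = unroll_views(bags)
        assert len(X) == len(bags) * 5
        expected = np.concatenate(
            [np.full(5, b.label, dtype=object) for b in bags]
        )
        assert (y == expected).all()

    def test_separable_views_classified_perfectly_in_training(self):
        bags = separable_bags()
        model = train_svm_mv(bags, seed=0)
        X, y = unroll_views(bags)
        preds = [model.classes[i] for i in model.decision_scores(X).argmax(axis=1)]
        assert (np.array(preds, dtype=object) == y).all()

    def test_training_is_deterministic(self):
        bags = separable_bags()
        m1 = train_svm_mv(bags, seed=4)
        m2 = train_svm_mv(bags, seed=4)
        assert np.array_equal(m1.weights, m2.weights)
        assert np.array_equal(m1.biases, m2.biases)

    def test_missing_class_rejected(self):
        bags = [b for b in separable_bags() if b.label != "sitting"]
        with pytest.raises(ValueError, match="sitting"):
            train_svm_mv(bags, classes=ACTION_CLASSES)


class TestPredictMv:
    def make_vote_model(self, dim=4):
        # weights hand-set so scores are directly controllable via one-hot inputs
        W = np.eye(4, dim)
        return LinearModel(
            ACTION_CLASSES, W, np.zeros(4), approach="SVM-MV", C=1.0, seed=0
        )

    def one_hot(self, idx, value=1.0, dim=4):
        x = np.zeros(dim)
        x[idx] = value
        return x

    def test_strict_majority_wins(self):
        model = self.make_vote_model()
        # votes: walking x3, sitting, standing
        emb = {
            0: self.one_hot(3),
            1: self.one_hot(3),
            2: self.one_hot(3),
            3: self.one_hot(1),
            4: self.one_hot(2),
        }
        bag = MultiViewActionInstance("x", emb)
        assert predict_mv(model, bag) == "walking"

    def test_vote_tie_broken_by_summed_scores_brute_force(self):
        model = self.make_vote_model()
        # 2 sitting votes, 2 standing votes, 1 walking; standing scores larger
        emb = {
            0: self.one_hot(1, 1.0),
            1: self.one_hot(1, 1.1),
            2: self.one_hot(2, 2.0),
            3: self.one_hot(2, 2.5),
            4: self.one_hot(3, 0.7),
        }
        bag = MultiViewActionInstance("x", emb)
        # brute-force re-computation of the tie-break
        scores = model.decision_scores(bag.matrix())
        votes = Counter(scores.argmax(axis=1))
        top = max(votes.values())
        tied = [c for c, n in votes.items() if n == top]
        expected = ACTION_CLASSES[max(tied, key=lambda c: scores[:, c].sum())]
        assert expected == "standing"
        assert predict_mv(model, bag) == expected

    def test_single_view_bag_returns_its_prediction(self):
        model = self.make_vote_model()
        bag = MultiViewActionInstance("x", {2: self.one_hot(0)})
        assert predict_mv(model, bag) == "crawling"

    def test_unanimous_views_immune_to_tiebreak(self):
        bags = separable_bags(identical_views=True)
        model = train_svm_mv(bags, seed=0)
        for bag in bags[:8]:
            scores = model.decision_scores(bag.matrix())
            per_view = {model.classes[i] for i in scores.argmax(axis=1)}
            if len(per_view) == 1:
                assert predict_mv(model, bag) == per_view.pop()


class TestMiSvm:
    def test_witness_recovery_on_planted_informative_views(self):
        """When one view per bag carries the class signal, the selected
        witnesses coincide with the informative views in >= 90% of bags."""
        rng = np.random.default_rng(0)
        dim = 10
        means = {c: 5.0 * rng.standard_normal(dim) for c in ACTION_CLASSES}
        bags, informative = [], {}
        for c in ACTION_CLASSES:
            for i in range(12):
                iid = f"{c}_{i}"
                witness_view = int(rng.integers(5))
                emb = {}
                for v in range(5):
                    if v == witness_view:
                        emb[v] = means[c] + 0.3 * rng.standard_normal(dim)
                    else:
                        emb[v] = 0.5 * rng.standard_normal(dim)  # background
                bags.append(MultiViewActionInstance(iid, emb, c))
                informative[iid] = witness_view
        model = train_mi_svm(bags, seed=0)
        hits = total = 0
        for bag in bags:
            i = model.classes.index(bag.label)
            scores = bag.matrix() @ model.weights[i] + model.biases[i]
            hits += int(np.argmax(scores)) == informative[bag.instance_id]
            total += 1
        assert hits / total >= 0.9

    def test_identical_views_reduce_to_plain_svm(self):
        # witness choice is vacuous when all views coincide; the learned
        # model matches a plain SVM on one view per bag (up to the extra
        # hinge weight the duplicated negative views carry)
        bags = separable_bags(identical_views=True)
        mi = train_mi_svm(bags, seed=0)
        one_view = [
            MultiViewActionInstance(b.instance_id, {0: b.embeddings[0]}, b.label)
            for b in bags
        ]
        sv = train_svm_mv(one_view, seed=0)
        assert np.allclose(mi.weights, sv.weights, atol=0.02)
        assert np.allclose(mi.biases, sv.biases, atol=0.02)
        for bag, single in zip(bags, one_view):
            assert predict_mi(mi, bag) == predict_mv(sv, single)

    def test_iteration_zero_is_label_transfer(self):
        """The documented initialization: every view of a positive bag starts
        as a candidate positive, i.e. the iteration-0 training set equals the
        label-transfer expansion."""
        bags = separable_bags(n_per_class=3)
        c = "crawling"
        pos = [b for b in bags if b.label == c]
        neg = [b for b in bags if b.label != c]
        X0 = np.concatenate(
            [b.matrix() for b in pos] + [b.matrix() for b in neg]
        )
        X_transfer, y_transfer = unroll_views(pos + neg)
        assert np.array_equal(X0, X_transfer)
        assert (y_transfer[: 5 * len(pos)] == c).all()

    def test_objective_history_is_monotone_nonincreasing(self, small_bags):
        model = train_mi_svm(small_bags[:60], seed=0)
        for objs in model.objective_history.values():
            diffs = np.diff(objs)
            # non-increasing up to the linear-SVM solver's tolerance
            assert (diffs <= 1e-4 * np.maximum(np.abs(objs[:-1]), 1.0)).all()

    def test_training_is_deterministic(self, small_bags):
        m1 = train_mi_svm(small_bags[:40], seed=2)
        m2 = train_mi_svm(small_bags[:40], seed=2)
        assert np.array_equal(m1.weights, m2.weights)


class TestPredictMi:
    def test_bag_score_is_max_over_views_brute_force(self, small_bags):
        model = train_mi_svm(small_bags[:40], seed=0)
        for bag in small_bags[40:60]:
            scores = bag_scores_mi(model, bag)
            brute = np.max(
                [model.decision_scores(bag.embeddings[v][None]) for v in bag.views],
                axis=0,
            ).ravel()
            assert np.allclose(scores, brute)
            assert predict_mi(model, bag) == model.classes[int(np.argmax(brute))]

    def test_one_strong_view_beats_noise_views(self):
        W = np.eye(4)
        model = LinearModel(
            ACTION_CLASSES, W, np.zeros(4), approach="MI-SVM", C=1.0, seed=0
        )
        emb = {0: np.array([0, 0, 0, 5.0])}
        for v in range(1, 5):
            emb[v] = np.full(4, 0.01)
        assert predict_mi(model, MultiViewActionInstance("x", emb)) == "walking"

    def test_exact_tie_breaks_by_class_order(self):
        model = LinearModel(
            ACTION_CLASSES, np.eye(4), np.zeros(4), approach="MI-SVM", C=1.0, seed=0
        )
        emb = {0: np.array([0.0, 3.0, 3.0, 0.0])}
        assert predict_mi(model, MultiViewActionInstance("x", emb)) == "sitting"

    def test_approach_mismatch_rejected(self, small_bags):
        model = train_svm_mv(small_bags[:40], seed=0)
        with pytest.raises(ValueError):
            predict_mi(model, small_bags[0])


class TestEvaluate:
    def test_perfect_classifier_on_clean_separable_bags(self):
        bags = separable_bags(n_per_class=10)
        plan = make_splits(bags, n_splits=2, seed=0)
        for approach in ("SVM-MV", "MI-SVM"):
            result = evaluate(approach, bags, plan, seed=0)
            assert result.mean_accuracy == 100.0
            assert np.allclose(np.diag(result.mean_confusion), 100.0)

    def test_confusion_rows_sum_to_one_hundred(self, small_bags):
        plan = make_splits(small_bags, n_splits=2, seed=0)
        result = evaluate("SVM-MV", small_bags, plan, seed=0)
        for conf in result.confusion_matrices:
            assert np.allclose(conf.sum(axis=1), 100.0, atol=0.1)

    def test_mi_svm_beats_majority_vote_under_occlusion(self):
        """On occlusion-corrupted bags the multiple-instance classifier is at
        least as accurate as majority-vote fusion, on identical splits."""
        bags = make_feature_bags(n_per_class=80, seed=0)
        plan = make_splits(bags, n_splits=5, seed=0)
        mv = evaluate("SVM-MV", bags, plan, seed=0)
        mi = evaluate("MI-SVM", bags, plan, seed=0)
        assert mi.mean_accuracy >= mv.mean_accuracy

    def test_confusion_plot_written(self, small_bags, tmp_path):
        from gearcri.multiview_classify import plot_confusion

        plan = make_splits(small_bags, n_splits=2, seed=0)
        result = evaluate("SVM-MV", small_bags, plan, seed=0)
        out = tmp_path / "confusion.png"
        plot_confusion(result, out)
        assert out.exists() and out.stat().st_size > 0

    def test_unknown_approach_rejected(self, small_bags):
        with pytest.raises(ValueError):
            evaluate("deep-net", small_bags, make_splits(small_bags, 1, seed=0))
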