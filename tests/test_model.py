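"""Focal loss, stratified splits, training protocol, and evaluation."""

import numpy as np
import pytest

from vgn.graph_builder import GraphFeatureScaler
from vgn.model import (
    SplitSpec,
    VGNClassifier,
    VGNConfig,
    _apportion,
    evaluate,
    focal_loss,
    inverse_frequency_weights,
    make_splits,
    train,
)

from conftest import make_graph


class TestFocalLoss:
    def test_gamma_zero_unit_weights_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        scores = rng.dirichlet(np.ones(5), size=1000)
        labels = rng.integers(0, 5, size=1000)
        fl = focal_loss(scores, labels, gamma=0.0)
        ce = float(np.mean(-np.log(scores[np.arange(1000), labels])))
        assert fl == pytest.approx(ce, abs=1e-6)

    def test_confident_correct_prediction_has_zero_loss(self):
        scores = np.array([[0.0, 1.0, 0.0, 0.0, 0.0]])
        assert focal_loss(scores, [1], gamma=2.0) == pytest.approx(0.0)

    def test_half_probability_gamma_two_hand_value(self):
        scores = np.full((1, 5), 0.125)
        scores[0, 2] = 0.5
        loss = focal_loss(scores, [2], gamma=2.0)
        assert loss == pytest.approx(0.25 * np.log(2), rel=1e-9)

    def test_zero_probability_is_clamped_not_infinite(self):
        scores = np.array([[1.0, 0.0, 0.0, 0.0, 0.0]])
        loss = focal_loss(scores, [1], gamma=2.0)
        assert np.isfinite(loss)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError, match="gamma"):
            focal_loss(np.full((1, 5), 0.2), [0], gamma=-1.0)

    def test_class_weights_scale_loss(self):
        scores = np.full((1, 5), 0.2)
        base = focal_loss(scores, [0], gamma=0.0)
        weighted = focal_loss(scores, [0], gamma=0.0,
                              class_weights=[3.0, 1, 1, 1, 1])
        assert weighted == pytest.approx(3 * base)


def test_inverse_frequency_weights_mean_one():
    labels = np.array([0] * 10 + [1] * 5 + [2] * 1)
    w = inverse_frequency_weights(labels, n_classes=5)
    present = w[[0, 1, 2]]
    assert present.mean() == pytest.approx(1.0)
    assert present[2] > present[1] > present[0]
    assert np.all(w[3:] == 1.0)  # absent classes neutral


class TestSplits:
    def test_exact_ratio_for_twenty(self):
        assert _apportion(20) == [15, 3, 2]

    def test_thirty_largest_remainder(self):
        assert _apportion(30) == [22, 5, 3]

    def test_eight_gets_one_val_one_test(self):
        assert _apportion(8) == [6, 1, 1]

    def test_same_seed_reproduces_splits(self):
        labels = {f"s{i:02d}": i % 5 for i in range(25)}
        a = make_splits(labels, n_repeats=3, seed=11)
        b = make_splits(labels, n_repeats=3, seed=11)
        for sa, sb in zip(a, b):
            assert sa.train == sb.train and sa.val == sb.val and sa.test == sb.test

    def test_splits_are_disjoint_and_stratified(self):
        labels = {f"s{i:02d}": i % 5 for i in range(40)}  # 8 per class
        for split in make_splits(labels, n_repeats=10, seed=0):
            ids = split.train + split.val + split.test
            assert len(set(ids)) == len(ids) == 40
            for part, expected in ((split.train, 6), (split.val, 1), (split.test, 1)):
                counts = np.bincount([labels[s] for s in part], minlength=5)
                assert np.all(counts == expected)

    def test_singleton_class_goes_to_training_with_warning(self):
        labels = {"a": 0, "b": 0, "c": 0, "lone": 1}
        with pytest.warns(RuntimeWarning, match="single specimen"):
            splits = make_splits(labels, n_repeats=1, seed=0)
        assert "lone" in splits[0].train

    def test_overlapping_split_spec_rejected(self):
        with pytest.raises(ValueError, match="two splits"):
            SplitSpec(train=["a", "b"], val=["b"], test=["c"])


def separable_graphs(n_per_class=20, n_nodes=5, shift=5.0, seed=0):
    """Two-class graphs whose features differ by ``shift`` standard deviations."""
    rng = np.random.default_rng(seed)
    graphs, labels = [], []
    for cls in (0, 1):
        for i in range(n_per_class):
            feats = rng.normal(cls * shift, 1.0, size=(n_nodes, 7))
            pos = np.column_stack([rng.uniform(0, 3e-3, n_nodes),
                                   np.zeros(n_nodes)])
            g = make_graph(pos, features=feats, label=cls,
                           specimen_id=f"c{cls}_{i}")
            graphs.append(g)
            labels.append(cls)
    return graphs, np.array(labels)


class TestTraining:
    def test_separable_classes_learned_quickly(self):
        graphs, labels = separable_graphs()
        scaled, _ = __import__("vgn").standardize_features(graphs)
        clf = VGNClassifier(epochs=50, milestones=(30, 40), batch_size=8, seed=0)
        clf.fit(scaled, labels)
        assert (clf.predict(scaled) == labels).mean() >= 0.99

    def test_fit_is_deterministic_for_fixed_seed(self):
        graphs, labels = separable_graphs(n_per_class=6)
        scaled, _ = __import__("vgn").standardize_features(graphs)
        p = []
        for _ in range(2):
            clf = VGNClassifier(epochs=3, batch_size=4, seed=7)
            clf.fit(scaled, labels)
            p.append(clf.predict_proba(scaled))
        assert np.array_equal(p[0], p[1])

    def test_recorded_lr_follows_multistep_schedule(self):
        graphs, labels = separable_graphs(n_per_class=3)
        clf = VGNClassifier(epochs=8, milestones=(3, 6), lr=1e-2, batch_size=4, seed=0)
        clf.fit(graphs, labels)
        lr = clf.history_["lr"]
        assert np.allclose(lr[:3], 1e-2)
        assert np.allclose(lr[3:6], 1e-3)
        assert np.allclose(lr[6:], 1e-4)

    def test_loss_decreases_on_separable_data(self):
        graphs, labels = separable_graphs(n_per_class=10)
        scaled, _ = __import__("vgn").standardize_features(graphs)
        clf = VGNClassifier(epochs=30, batch_size=8, seed=0)
        clf.fit(scaled, labels)
        loss = np.array(clf.history_["loss"])
        assert loss[-5:].mean() < 0.1 * loss[:5].mean()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            VGNClassifier().fit([], [])

    def test_train_wrapper_standardizes_on_training_split_only(self):
        graphs, _ = separable_graphs(n_per_class=6)
        split = SplitSpec(
            train=[g.specimen_id for g in graphs[:4] + graphs[6:10]],
            val=[graphs[4].specimen_id, graphs[10].specimen_id],
            test=[graphs[5].specimen_id, graphs[11].specimen_id],
        )
        cfg = VGNConfig(epochs=2, batch_size=4, seed=0)
        clf, scaler, history = train(graphs, split, cfg)
        manual = GraphFeatureScaler().fit(
            [g for g in graphs if g.specimen_id in set(split.train)]
        )
        assert np.allclose(scaler.mean_, manual.mean_)
        assert len(history["loss"]) == 2


class StubClassifier:
    """Duck-typed stand-in returning preset scores, for metric tests."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, X):
        return self.scores[: len(X)]


def brute_force_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Exhaustive-threshold trapezoid AUC (probability-of-correct-ranking form)."""
    thresholds = np.unique(np.concatenate([[-np.inf], np.sort(scores), [np.inf]]))
    pts = []
    pos, neg = (y_true == 1).sum(), (y_true == 0).sum()
    for th in thresholds:
        pred = scores >= th
        tpr = (pred & (y_true == 1)).sum() / pos
        fpr = (pred & (y_true == 0)).sum() / neg
        pts.append((fpr, tpr))
    pts = sorted(pts)
    area = 0.0
    for (f0, t0), (f1, t1) in zip(pts, pts[1:]):
        area += (f1 - f0) * (t0 + t1) / 2
    return area


class TestEvaluate:
    def graphs_with_labels(self, labels):
        return [
            make_graph(np.array([[0.0, 0], [1e-3, 0]]),
                       features=np.zeros((2, 7)), label=int(l),
                       specimen_id=f"s{i}")
            for i, l in enumerate(labels)
        ]

    def test_perfect_scores_give_identity_confusion_and_unit_auc(self):
        labels = np.repeat(np.arange(5), 4)
        scores = np.eye(5)[labels]
        res = evaluate(StubClassifier(scores), self.graphs_with_labels(labels), labels)
        assert np.allclose(res["confusion"], np.eye(5))
        assert np.allclose(res["auc"], 1.0)
        assert res["accuracy"] == pytest.approx(1.0)

    def test_random_scores_give_chance_level_auc(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(np.arange(5), 80)
        scores = rng.dirichlet(np.ones(5), size=400)
        res = evaluate(StubClassifier(scores), self.graphs_with_labels(labels), labels)
        assert np.all(np.abs(res["auc"] - 0.5) < 0.08)

    def test_auc_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=20)
        s1 = rng.uniform(size=20)
        scores = np.column_stack([1 - s1, s1, np.zeros((20, 3))])
        scores /= scores.sum(axis=1, keepdims=True)
        res = evaluate(StubClassifier(scores), self.graphs_with_labels(labels),
                       labels)
        assert res["auc"][1] == pytest.approx(brute_force_auc(labels, scores[:, 1]))

    def test_absent_class_is_undefined_and_excluded(self):
        labels = np.array([0, 0, 1, 1])  # classes 2-4 absent
        scores = np.eye(5)[labels]
        res = evaluate(StubClassifier(scores), self.graphs_with_labels(labels), labels)
        assert np.isnan(res["confusion"][2]).all()
        assert np.isnan(res["auc"][2])
        assert res["accuracy"] == pytest.approx(1.0)

    def test_empty_test_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(StubClassifier(np.zeros((0, 5))), [], [])
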