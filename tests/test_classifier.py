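import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vtpred.classifier import (EvalReport, MLPModel, TrainConfig, auc_brute,
                               classify, evaluate, predict, select_hidden_size,
                               split_stratified, train_mlp)


def two_clusters(n_per_class, d=4, separation=6.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.standard_normal((n_per_class, d)) + separation,
                   rng.standard_normal((n_per_class, d))])
    y = np.concatenate([np.ones(n_per_class), -np.ones(n_per_class)])
    return x, y


class TestSplitStratified:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_52_52_gives_35_17_per_class(self, seed):
        labels = np.array([1] * 52 + [-1] * 52)
        train, test = split_stratified(labels, 2 / 3, seed=seed)
        assert len(train) == 70 and len(test) == 34
        assert (labels[train] == 1).sum() == 35
        assert (labels[test] == 1).sum() == 17
        assert sorted(np.concatenate([train, test])) == list(range(104))

    def test_full_fraction_rejected(self):
        labels = np.array([1] * 10 + [-1] * 10)
        with pytest.raises(ValueError, match="empty test"):
            split_stratified(labels, 1.0)

    def test_deterministic(self):
        labels = np.array([1] * 20 + [-1] * 20)
        a = split_stratified(labels, 2 / 3, seed=9)
        b = split_stratified(labels, 2 / 3, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_small_class_rejected(self):
        labels = np.array([1, 1, -1, -1, -1, -1])
        with pytest.raises(ValueError, match="fewer than 3"):
            split_stratified(labels, 2 / 3)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            split_stratified(np.ones(10), 2 / 3)


class TestTrainMlp:
    def test_xor_reaches_mse_target(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([-1.0, 1.0, 1.0, -1.0])
        converged = False
        for seed in range(10):
            model = train_mlp(x, y, 5, TrainConfig(lr=0.1, max_epochs=50000,
                                                   seed=seed))
            if model.converged:
                converged = True
                assert model.final_mse < 1e-5
                break
        assert converged

    def test_separated_clusters_perfect_train_accuracy(self):
        x, y = two_clusters(30)
        model = train_mlp(x, y, 5, TrainConfig(max_epochs=2000, seed=0))
        assert np.all(classify(predict(model, x)) == y)

    def test_single_example_per_class(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.5]])
        y = np.array([1.0, -1.0])
        model = train_mlp(x, y, 3, TrainConfig(max_epochs=2000, seed=1))
        scores = predict(model, x)
        assert np.sign(scores[0]) != np.sign(scores[1])

    def test_mse_nonincreasing_without_momentum(self):
        x, y = two_clusters(20, seed=5)
        mses = []
        for epochs in (1, 5, 20, 80, 320):
            m = train_mlp(x, y, 5, TrainConfig(lr=0.001, momentum=0.0,
                                               max_epochs=epochs, seed=3))
            mses.append(m.final_mse)
        assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))

    def test_reproducible(self):
        x, y = two_clusters(15, seed=2)
        cfg = TrainConfig(max_epochs=200, seed=11)
        a = train_mlp(x, y, 4, cfg)
        b = train_mlp(x, y, 4, cfg)
        np.testing.assert_array_equal(a.w1, b.w1)
        np.testing.assert_array_equal(a.w2, b.w2)
        assert a.final_mse == b.final_mse

    def test_bad_inputs(self):
        x, y = two_clusters(5)
        with pytest.raises(ValueError, match="n_hidden"):
            train_mlp(x, y, 0)
        with pytest.raises(ValueError, match="non-finite"):
            train_mlp(x * np.nan, y, 3)
        with pytest.raises(ValueError, match="both classes"):
            train_mlp(x, np.ones_like(y), 3)


class TestPredict:
    def test_zero_weights_score_zero(self):
        model = MLPModel(w1=np.zeros((3, 2)), b1=np.zeros(2), w2=np.zeros(2),
                         b2=0.0, norm_mean=np.zeros(3), norm_std=np.ones(3))
        assert predict(model, np.array([1.0, -2.0, 3.0])) == 0.0

    def test_shift_absorbed_by_normalization(self):
        x, y = two_clusters(20, seed=8)
        shift = np.array([100.0, -50.0, 3.0, 0.1])
        cfg = TrainConfig(max_epochs=300, seed=2)
        a = predict(train_mlp(x, y, 4, cfg), x + 0.0)
        b = predict(train_mlp(x + shift, y, 4, cfg), x + shift)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_monotone_single_unit(self):
        model = MLPModel(w1=np.array([[2.0]]), b1=np.zeros(1), w2=np.array([1.5]),
                         b2=0.0, norm_mean=np.zeros(1), norm_std=np.ones(1))
        xs = np.linspace(-3, 3, 50)[:, None]
        scores = predict(model, xs)
        assert np.all(np.diff(scores) > 0)

    def test_dimension_mismatch(self):
        model = MLPModel(w1=np.zeros((3, 2)), b1=np.zeros(2), w2=np.zeros(2),
                         b2=0.0, norm_mean=np.zeros(3), norm_std=np.ones(3))
        with pytest.raises(ValueError, match="features"):
            predict(model, np.zeros(5))

    def test_zero_score_classified_control(self):
        assert classify(np.array([0.0]))[0] == -1


class TestEvaluate:
    def test_combined_model_worked_example(self):
        report = EvalReport.from_counts(tp=15, fn=2, tn=14, fp=3)
        assert round(100 * report.sensitivity, 1) == 88.2
        assert round(100 * report.specificity, 1) == 82.4
        assert round(100 * report.accuracy, 1) == 85.3
        assert round(100 * report.ppv, 1) == 83.3
        assert round(100 * report.npv, 1) == 87.5

    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0])
        labels = np.array([1, 1, 1, -1, -1, -1])
        report = evaluate(scores, labels)
        assert (report.tp, report.fn, report.tn, report.fp) == (3, 0, 3, 0)
        assert report.accuracy == 1.0
        assert report.auc == 1.0

    def test_identical_scores_auc_half(self):
        report = evaluate(np.zeros(10), np.array([1] * 5 + [-1] * 5))
        assert report.auc == pytest.approx(0.5)

    def test_roc_endpoints_monotone(self, rng):
        scores = rng.standard_normal(40)
        labels = np.sign(rng.standard_normal(40)) + 0.0
        labels[labels == 0] = 1
        report = evaluate(scores, labels)
        fpr, tpr = zip(*report.roc)
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            evaluate(np.zeros(4), np.ones(4))

    def test_counts_identities(self, rng):
        scores = rng.standard_normal(30)
        labels = np.array([1] * 14 + [-1] * 16)
        r = evaluate(scores, labels)
        assert r.tp + r.fn == 14 and r.tn + r.fp == 16
        assert r.accuracy == (r.tp + r.tn) / 30
        assert r.sensitivity * (r.tp + r.fn) == pytest.approx(r.tp)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.standard_normal(60)
        labels = np.array([1] * 30 + [-1] * 30)
        report = evaluate(scores, labels)
        assert report.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestAucBrute:
    def test_separated(self):
        assert auc_brute(np.array([3.0, 2.0, 1.0, 0.0]),
                         np.array([1, 1, -1, -1])) == 1.0

    def test_tie_is_half(self):
        assert auc_brute(np.array([1.0, 1.0]), np.array([1, -1])) == 0.5

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_trapezoid_equals_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        # round to few digits so ties actually occur
        scores = np.round(rng.standard_normal(n), 1)
        labels = rng.choice([-1, 1], n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 1, -1
        report = evaluate(scores, labels)
        assert report.auc == pytest.approx(auc_brute(scores, labels), abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_label_swap_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(30)
        labels = np.array([1] * 15 + [-1] * 15)
        assert auc_brute(scores, labels) == pytest.approx(
            auc_brute(-scores, -labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_brute(np.zeros(3), np.ones(3))


class TestSerialization:
    def test_json_round_trip_exact(self, tmp_path):
        x, y = two_clusters(10, seed=4)
        model = train_mlp(x, y, 3, TrainConfig(max_epochs=50, seed=6))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MLPModel.from_json(path)
        np.testing.assert_array_equal(model.w1, back.w1)
        np.testing.assert_array_equal(model.b1, back.b1)
        np.testing.assert_array_equal(model.w2, back.w2)
        assert model.b2 == back.b2
        np.testing.assert_array_equal(model.norm_mean, back.norm_mean)
        assert model.final_mse == back.final_mse
        assert model.epochs_run == back.epochs_run


class TestSelectHiddenSize:
    def test_returns_candidate(self):
        x, y = two_clusters(30, seed=3)
        h = select_hidden_size(x, y, candidates=range(1, 4), seed=0,
                               cfg=TrainConfig(max_epochs=200))
        assert h in range(1, 4)
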