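"""Deep neural decision forest: routing algebra, training, evaluation."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs

from imupipe.dndf import DNDFClassifier, build_dndf, evaluate

SMALL = dict(hidden_layers=(32,), embed_dim=16, n_trees=5, tree_depth=4,
             epochs=30, random_state=0)


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(n_samples=400, centers=2, cluster_std=0.1,
                      center_box=(-1.0, 1.0), random_state=1)
    return X, y


@pytest.fixture(scope="module")
def fitted(blobs):
    X, y = blobs
    return DNDFClassifier(**SMALL).fit(X, y)


class TestConstruction:
    def test_embedding_output_width_matches_config(self):
        model = build_dndf(input_dim=740, n_classes=4, hidden_layers=(64,),
                           embed_dim=128, n_trees=2, tree_depth=3,
                           random_state=0)
        W_out = model.params_["layers"][-1][0]
        assert W_out.shape[1] == 128
        assert model.params_["layers"][0][0].shape[0] == 740

    def test_untrained_leaves_are_uniform(self):
        model = build_dndf(input_dim=10, n_classes=5, **SMALL)
        np.testing.assert_allclose(model.leaf_distributions(), 0.2, atol=1e-12)

    def test_same_seed_same_parameters(self):
        a = build_dndf(input_dim=12, n_classes=3, **SMALL)
        b = build_dndf(input_dim=12, n_classes=3, **SMALL)
        for (Wa, ba), (Wb, bb) in zip(a.params_["layers"], b.params_["layers"]):
            np.testing.assert_array_equal(Wa, Wb)
        np.testing.assert_array_equal(a.params_["Wr"], b.params_["Wr"])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_dndf(input_dim=5, n_classes=2, n_trees=0)


class TestRoutingAlgebra:
    def test_leaf_reach_probabilities_sum_to_one(self, fitted, blobs):
        mu = fitted.routing_probabilities(blobs[0][:50])
        np.testing.assert_allclose(mu.sum(axis=-1), 1.0, atol=1e-6)

    def test_prediction_rows_sum_to_one(self, fitted, blobs):
        p = fitted.predict_proba(blobs[0])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_depth_one_tree_mixes_leaves_equally(self):
        model = build_dndf(input_dim=3, n_classes=2, hidden_layers=(4,),
                           embed_dim=4, n_trees=1, tree_depth=1,
                           random_state=0)
        model.params_["Wr"][:] = 0.0
        model.params_["br"][:] = 0.0
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = 3
        model.standardize = False
        X = np.random.default_rng(0).normal(size=(10, 3))
        mu = model.routing_probabilities(X)
        np.testing.assert_allclose(mu, 0.5, atol=1e-12)
        np.testing.assert_allclose(model.predict_proba(X), 0.5, atol=1e-12)

    def test_predict_is_argmax_of_proba(self, fitted, rng):
        X = rng.normal(size=(100, 2))
        pred = fitted.predict(X)
        proba = fitted.predict_proba(X)
        np.testing.assert_array_equal(pred,
                                      fitted.classes_[np.argmax(proba, axis=1)])


class TestTraining:
    def test_separable_blobs_reach_99_percent(self, fitted, blobs):
        X, y = blobs
        assert (fitted.predict(X) == y).mean() >= 0.99
        assert len(fitted.loss_trace_) == SMALL["epochs"]

    def test_loss_trend_decreases(self, fitted):
        trace = np.asarray(fitted.loss_trace_)
        k = max(3, len(trace) // 5)
        assert trace[-k:].mean() < trace[:k].mean()

    def test_shuffled_labels_stay_at_chance(self, blobs):
        X, y = blobs
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        tr, te = np.arange(300), np.arange(300, 400)
        clf = DNDFClassifier(**SMALL).fit(X[tr], y_shuf[tr])
        acc = (clf.predict(X[te]) == y_shuf[te]).mean()
        sigma = np.sqrt(0.25 / len(te))
        assert abs(acc - 0.5) <= 3 * sigma + 1e-12

    def test_training_reproducible_given_seed(self, blobs):
        X, y = blobs
        cfg = dict(SMALL, epochs=5)
        a = DNDFClassifier(**cfg).fit(X, y)
        b = DNDFClassifier(**cfg).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_more_trees_do_not_hurt(self):
        accs = {1: [], 10: []}
        for seed in range(5):
            X, y = make_blobs(n_samples=240, centers=3, cluster_std=0.6,
                              random_state=seed)
            tr = np.arange(180)
            te = np.arange(180, 240)
            for n_trees in (1, 10):
                clf = DNDFClassifier(hidden_layers=(16,), embed_dim=8,
                                     n_trees=n_trees, tree_depth=3, epochs=20,
                                     random_state=seed).fit(X[tr], y[tr])
                accs[n_trees].append((clf.predict(X[te]) == y[te]).mean())
        assert np.mean(accs[10]) >= np.mean(accs[1]) - 0.05

    def test_dimension_mismatch_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.predict(np.ones((3, 7)))

    def test_untrained_model_rejected(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            DNDFClassifier(**SMALL).predict(np.ones((2, 3)))

    def test_save_load_roundtrip(self, fitted, blobs, tmp_path):
        path = tmp_path / "model.npz"
        fitted.save(path)
        back = DNDFClassifier.load(path)
        np.testing.assert_allclose(back.predict_proba(blobs[0]),
                                   fitted.predict_proba(blobs[0]), atol=1e-12)


def metric_oracle(y_true, y_pred, labels):
    """Hand-rolled confusion counter and per-class metrics."""
    idx = {c: i for i, c in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)))
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    prec, rec, f1 = [], [], []
    for i in range(len(labels)):
        tp = cm[i, i]
        p = tp / cm[:, i].sum() if cm[:, i].sum() else 0.0
        r = tp / cm[i, :].sum() if cm[i, :].sum() else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(2 * p * r / (p + r) if (p + r) else 0.0)
    acc = np.trace(cm) / cm.sum()
    return cm, np.array(prec), np.array(rec), np.array(f1), acc


class TestEvaluate:
    def test_perfect_predictions_identity_confusion(self, fitted, blobs):
        X, y = blobs
        m = evaluate(fitted, X, y)     # fitted is ~perfect on blobs
        if m["accuracy"] == 1.0:
            np.testing.assert_allclose(m["confusion_normalized"], np.eye(2))
            assert m["macro_f1"] == 1.0

    def test_matches_handrolled_oracle(self, fitted, blobs, rng):
        X, _ = blobs
        y_rand = rng.integers(0, 2, size=len(X))
        m = evaluate(fitted, X, y_rand)
        y_pred = fitted.predict(X)
        cm, prec, rec, f1, acc = metric_oracle(y_rand, y_pred, m["labels"])
        np.testing.assert_allclose(m["confusion"], cm, atol=1e-9)
        np.testing.assert_allclose(m["precision"], prec, atol=1e-9)
        np.testing.assert_allclose(m["recall"], rec, atol=1e-9)
        np.testing.assert_allclose(m["f1"], f1, atol=1e-9)
        assert m["accuracy"] == pytest.approx(acc, abs=1e-9)

    def test_constant_predictor_closed_form(self):
        class Constant:
            classes_ = np.array([0, 1])

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        X = np.zeros((100, 2))
        y = np.repeat([0, 1], 50)
        m = evaluate(Constant(), X, y)
        assert m["accuracy"] == 0.5
        assert m["recall"][0] == 1.0
        assert m["recall"][1] == 0.0

    def test_unknown_label_rejected(self, fitted, blobs):
        X, y = blobs
        bad = y.copy()
        bad[0] = 99
        with pytest.raises(ValueError):
            evaluate(fitted, X, bad)
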