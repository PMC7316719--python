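"""Classifier training, scoring, symmetry and serialization."""

import numpy as np
import pytest

from ssbondnet import (DisulfideBondClassifier, classify, load_model,
                       save_model, score, swap_pair_order)
from ssbondnet.evaluation import roc
from ssbondnet.features import N_FEATURES
from ssbondnet.model import ModelFormatError


def _gaussian_clouds(n_per_class=1000, separation=10.0, sigma=1.0, seed=0):
    """Two isotropic 45-d Gaussian clouds separated along every axis by
    ``separation`` (10 sigma by default): linearly separable by construction."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(loc=3.0, scale=sigma, size=(n_per_class, N_FEATURES))
    X1 = rng.normal(loc=3.0 + separation, scale=sigma, size=(n_per_class, N_FEATURES))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
    return X, y


class TestTraining:
    def test_separable_clouds_reach_high_training_accuracy(self):
        X, y = _gaussian_clouds(n_per_class=1000)
        clf = DisulfideBondClassifier(random_state=0).fit(X, y)
        assert clf.training_log_[-1]["accuracy"] >= 0.99

    def test_training_is_bit_reproducible(self, cloud_dataset):
        a = DisulfideBondClassifier(random_state=5).fit(
            cloud_dataset.X_train, cloud_dataset.y_train)
        b = DisulfideBondClassifier(random_state=5).fit(
            cloud_dataset.X_train, cloud_dataset.y_train)
        for wa, wb in zip(a.weights_, b.weights_):
            assert np.array_equal(wa, wb)
        for ba, bb in zip(a.biases_, b.biases_):
            assert np.array_equal(ba, bb)

    def test_geometric_benchmark_heldout_auc(self, cloud_dataset, trained_classifier):
        p = trained_classifier.predict_proba(cloud_dataset.X_test)[:, 1]
        assert roc(p, cloud_dataset.y_test).auc >= 0.95

    def test_loss_decreases_from_first_to_last_epoch(self, trained_classifier):
        log = trained_classifier.training_log_
        assert len(log) == 10
        assert log[-1]["loss"] <= log[0]["loss"]

    def test_multivariate_structure_beats_single_features(self):
        # label depends on the SUM of two features; each alone is weakly
        # informative, so beating every single-feature AUC requires the net
        # to combine them
        rng = np.random.default_rng(11)
        X = rng.normal(size=(4000, N_FEATURES))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        clf = DisulfideBondClassifier(symmetrize=False, random_state=0)
        clf.fit(X[:3000], y[:3000])
        p = clf.predict_proba(X[3000:])[:, 1]
        net_auc = roc(p, y[3000:]).auc
        single = max(
            max(roc(X[3000:, k], y[3000:]).auc,
                1 - roc(X[3000:, k], y[3000:]).auc)
            for k in range(N_FEATURES))
        assert net_auc > single

    def test_single_class_and_bad_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, N_FEATURES))
        with pytest.raises(ValueError, match="single class"):
            DisulfideBondClassifier().fit(X, np.zeros(50, int))
        with pytest.raises(ValueError):
            DisulfideBondClassifier().fit(X, np.arange(50) % 3)


class TestScoring:
    def test_scores_in_unit_interval(self, trained_classifier, cloud_dataset):
        p = trained_classifier.predict_proba(cloud_dataset.X)[:, 1]
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_score_exactly_symmetric_under_pair_swap(self, trained_classifier,
                                                     cloud_dataset):
        X = cloud_dataset.X_test[:200]
        p = trained_classifier.predict_proba(X)[:, 1]
        p_sw = trained_classifier.predict_proba(swap_pair_order(X))[:, 1]
        assert np.array_equal(p, p_sw)

    def test_forward_pass_matches_explicit_composition(self):
        # tiny hand-built network: verify the forward pass against plain
        # affine+ReLU+logistic arithmetic computed independently
        clf = DisulfideBondClassifier(hidden_sizes=(3, 2), symmetrize=False)
        clf.n_features_in_ = 4
        clf.classes_ = np.array([0, 1])
        rng = np.random.default_rng(3)
        sizes = [4, 3, 2, 1]
        clf.weights_ = [rng.normal(size=(a, b))
                        for a, b in zip(sizes[:-1], sizes[1:])]
        clf.biases_ = [rng.normal(size=b) for b in sizes[1:]]
        x = rng.normal(size=(1, 4))
        h1 = np.maximum(x @ clf.weights_[0] + clf.biases_[0], 0)
        h2 = np.maximum(h1 @ clf.weights_[1] + clf.biases_[1], 0)
        z = float((h2 @ clf.weights_[2] + clf.biases_[2])[0, 0])
        expected = 1.0 / (1.0 + np.exp(-z))
        got = clf.predict_proba(x)[0, 1]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_threshold_boundary_and_overrides(self, trained_classifier,
                                              cloud_dataset):
        f = cloud_dataset.X_test[0]
        s = score(trained_classifier, f)
        assert classify(trained_classifier, f) == (
            "bonded" if s >= 0.5 else "nonbonded")
        lo = DisulfideBondClassifier(threshold=0.3)
        hi = DisulfideBondClassifier(threshold=0.7)
        for attr in ("weights_", "biases_", "n_features_in_", "classes_",
                     "training_log_"):
            setattr(lo, attr, getattr(trained_classifier, attr))
            setattr(hi, attr, getattr(trained_classifier, attr))
        mid_scores = trained_classifier.predict_proba(cloud_dataset.X_test)[:, 1]
        mid = cloud_dataset.X_test[(mid_scores > 0.3) & (mid_scores < 0.7)]
        if len(mid):
            assert lo.predict(mid[:1])[0] == 1
            assert hi.predict(mid[:1])[0] == 0

    def test_wrong_feature_length_rejected(self, trained_classifier):
        with pytest.raises(ValueError):
            trained_classifier.predict_proba(np.zeros((1, 10)))


class TestSerialization:
    def test_round_trip_scores_bit_identical(self, trained_classifier,
                                             cloud_dataset, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained_classifier, path)
        back = load_model(path)
        probes = cloud_dataset.X[:100]
        assert np.array_equal(trained_classifier.predict_proba(probes),
                              back.predict_proba(probes))
        assert back.get_params() == trained_classifier.get_params()

    def test_truncated_file_raises(self, trained_classifier, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained_classifier, path)
        path.write_text(path.read_text()[: path.stat().st_size // 2])
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_shape_mismatch_raises(self, trained_classifier, tmp_path):
        import json
        path = tmp_path / "model.json"
        save_model(trained_classifier, path)
        payload = json.loads(path.read_text())
        payload["weights"][0] = payload["weights"][0][:10]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFormatError, match="inconsistent"):
            load_model(path)
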