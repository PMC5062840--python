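import numpy as np
import pytest

from cnqc.classifier import (
    RELIABLE,
    UNRELIABLE,
    TrainingSet,
    cross_validate,
    predict,
    roc_auc,
    subcategorize,
    train_model,
)
from cnqc.features import FeatureVector


def gaussian_training_set(seed=0, n_per_class=20, separation=5.0):
    rng = np.random.default_rng(seed)
    fvs, labels = [], []
    for i in range(n_per_class):
        a = rng.normal([2.0, 40, 60, 0.15], 0.3)
        fvs.append(FeatureVector(f"r{i}", *a))
        labels.append(RELIABLE)
    for i in range(n_per_class):
        b = rng.normal([2.0 + separation, 40 + 10 * separation, 60 + 50 * separation, 0.15 + 0.1 * separation], 0.3)
        fvs.append(FeatureVector(f"u{i}", *b))
        labels.append(UNRELIABLE)
    return TrainingSet(fvs, labels)


class TestTrainModel:
    def test_separable_clusters_fit_perfectly(self):
        ts = gaussian_training_set()
        model = train_model(ts)
        preds = [predict(model, fv)[0] for fv in ts.features]
        assert preds == ts.labels

    def test_serialization_roundtrip_preserves_predictions(self, tmp_path):
        ts = gaussian_training_set(seed=3)
        model = train_model(ts)
        path = tmp_path / "model.json"
        model.save(path)
        from cnqc.classifier import ReliabilityModel

        back = ReliabilityModel.load(path)
        rng = np.random.default_rng(9)
        X = rng.normal([3.0, 50, 100, 0.3], [2.0, 30, 80, 0.2], size=(100, 4))
        assert np.array_equal(model.predict_label(X), back.predict_label(X))
        assert np.allclose(model.predict_proba_unreliable(X), back.predict_proba_unreliable(X), atol=0)

    def test_training_order_invariance(self):
        ts = gaussian_training_set(seed=5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ts.labels))
        shuffled = TrainingSet([ts.features[i] for i in perm], [ts.labels[i] for i in perm])
        m1, m2 = train_model(ts), train_model(shuffled)
        X = np.random.default_rng(2).normal([3.0, 50, 100, 0.3], [2.0, 30, 80, 0.2], size=(50, 4))
        assert np.array_equal(m1.predict_label(X), m2.predict_label(X))

    def test_single_class_rejected(self):
        ts = gaussian_training_set()
        with pytest.raises(ValueError):
            train_model(TrainingSet(ts.features, [RELIABLE] * len(ts.labels)))

    def test_tiny_training_set_rejected(self):
        ts = gaussian_training_set(n_per_class=1)
        with pytest.raises(ValueError):
            train_model(ts)


class TestCrossValidate:
    def test_separable_set_scores_high(self):
        assert cross_validate(gaussian_training_set(n_per_class=30), folds=5, seed=0)[0] >= 0.95

    def test_shuffled_labels_score_at_chance(self):
        ts = gaussian_training_set(seed=7, n_per_class=40)
        rng = np.random.default_rng(4)
        means = []
        for _ in range(5):
            null = TrainingSet(ts.features, list(rng.permutation(ts.labels)))
            means.append(cross_validate(null, folds=5, seed=0)[0])
        assert abs(np.mean(means) - 0.5) <= 0.1

    def test_deterministic_given_seed(self):
        ts = gaussian_training_set(seed=11)
        assert cross_validate(ts, folds=4, seed=3) == cross_validate(ts, folds=4, seed=3)

    def test_folds_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(gaussian_training_set(n_per_class=4), folds=6)


class TestPredict:
    def test_probabilities_lie_in_unit_interval_and_complement(self):
        ts = gaussian_training_set()
        model = train_model(ts)
        _, p = predict(model, ts.features[0])
        assert 0.0 <= p <= 1.0  # P(reliable) is 1 - p by construction

    def test_non_finite_feature_rejected(self):
        model = train_model(gaussian_training_set())
        with pytest.raises(ValueError, match="non-finite"):
            predict(model, FeatureVector("bad", np.nan, 1, 22, 0.1))

    def test_sigma_sweep_flips_reliable_to_unreliable(self, trained_model, cohort_features):
        from .conftest import median_feature

        base = {
            "S_peak": median_feature(cohort_features, "A", "S_peak"),
            "l": median_feature(cohort_features, "A", "l"),
            "v": median_feature(cohort_features, "A", "v"),
        }
        labels = []
        for sigma in np.linspace(0.1, 1.2, 23):
            fv = FeatureVector("sweep", base["S_peak"], base["l"], base["v"], sigma)
            labels.append(predict(trained_model, fv)[0])
        assert labels[0] == RELIABLE
        assert UNRELIABLE in labels
        # once unreliable, staying unreliable as sigma keeps growing
        first = labels.index(UNRELIABLE)
        assert all(l == UNRELIABLE for l in labels[first:])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=2000)
        labels = rng.permutation([0, 1] * 1000)
        assert 0.45 <= roc_auc(scores, labels) <= 0.55

    def test_matches_pairwise_oracle_and_reference_implementation(self):
        rng = np.random.default_rng(25)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 2, size=50)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)
        from sklearn.metrics import roc_auc_score

        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestSubcategorize:
    def test_pure_function_of_inputs(self, trained_model, cohort_features):
        _, fv = cohort_features[0]
        a1 = subcategorize(trained_model, fv)
        a2 = subcategorize(trained_model, fv)
        assert a1 == a2

    def test_case_label_consistency_across_cohort(self, trained_model, cohort_features):
        for _, fv in cohort_features[::7]:
            a = subcategorize(trained_model, fv)
            if a.label == RELIABLE:
                assert a.case in (2, 5)
            else:
                assert a.case in (1, 3, 4)
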