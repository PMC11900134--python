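"""Model contracts: search, CV, determinism, gain importance, bundles."""

import numpy as np
import pytest

from gpcrscreen.chem_io import CompoundRecord, SiteMode
from gpcrscreen.curation import DEFAULT_CLASS_SCHEME
from gpcrscreen.featurize import FingerprintSpec, featurize_set
from gpcrscreen.models import (ActivityClassifier, ClassifierSearchSpace,
                               DegenerateLabelsError, PChEMBLRegressor,
                               RegressorSearchSpace, TrainedModelBundle,
                               UnsupportedModelError, gain_importance,
                               importance_report, predict_profile_leg,
                               train_classifier, train_regressor)
from gpcrscreen.synthetic import generate_classification_embedding

SMALL_CLF = dict(n_hidden_layers=(5, 6), units_per_layer=(16, 48),
                 n_trials=2, max_iter=150, random_state=0)


@pytest.fixture(scope="module")
def embedding():
    return generate_classification_embedding(n=200, n_bits=64, seed=5)


@pytest.fixture(scope="module")
def fitted_classifier(embedding):
    X, y = embedding
    return ActivityClassifier(**SMALL_CLF).fit(X, y)


class TestSearchSpaces:
    def test_estimator_range_bounded(self):
        with pytest.raises(ValueError, match="outside"):
            RegressorSearchSpace(n_estimators=(10, 100))
        with pytest.raises(ValueError, match="outside"):
            RegressorSearchSpace(n_estimators=(50, 100_000))

    def test_estimator_range_enforced_at_fit(self):
        X = np.random.default_rng(0).integers(0, 2, (20, 8)).astype(np.uint8)
        with pytest.raises(ValueError, match="outside"):
            PChEMBLRegressor(n_estimators=(1, 10)).fit(X, np.zeros(20))

    def test_classifier_space_validation(self):
        with pytest.raises(ValueError):
            ClassifierSearchSpace(n_trials=0)
        with pytest.raises(ValueError):
            ClassifierSearchSpace(n_hidden_layers=(20, 5))


class TestClassifier:
    def test_probabilities_sum_to_one_over_six_classes(self, fitted_classifier,
                                                       embedding):
        X, _ = embedding
        probs = fitted_classifier.predict_proba(X[:10])
        assert probs.shape == (10, 6)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_planted_signal_beats_majority_baseline(self, fitted_classifier,
                                                    embedding):
        """Perfectly separable planted labels: CV accuracy far above chance."""
        _, y = embedding
        majority = np.bincount(y).max() / len(y)
        assert fitted_classifier.cv_scores_.mean() >= majority + 0.2

    def test_ten_cv_folds_recorded(self, fitted_classifier):
        assert len(fitted_classifier.cv_scores_) == 10

    def test_argmax_label_in_range(self, fitted_classifier, embedding):
        X, _ = embedding
        preds = fitted_classifier.predict(X[:20])
        assert set(preds) <= set(range(6))

    def test_single_class_is_degenerate(self):
        X = np.random.default_rng(0).integers(0, 2, (20, 16)).astype(np.uint8)
        with pytest.raises(DegenerateLabelsError):
            ActivityClassifier(**SMALL_CLF).fit(X, np.ones(20, dtype=int))

    def test_width_mismatch_at_predict(self, fitted_classifier):
        with pytest.raises(ValueError):
            fitted_classifier.predict_proba(np.zeros((2, 99)))

    def test_seeded_reproducibility(self, embedding):
        X, y = embedding
        a = ActivityClassifier(**SMALL_CLF).fit(X, y)
        b = ActivityClassifier(**SMALL_CLF).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert np.allclose(a.cv_scores_, b.cv_scores_)

    def test_wrapper_returns_triple(self, embedding):
        X, y = embedding
        space = ClassifierSearchSpace(n_hidden_layers=(5, 6),
                                      units_per_layer=(16, 32), n_trials=1)
        predictor, cv, params = train_classifier(X, y, space, max_iter=100)
        assert len(cv) == 10
        assert 5 <= len(params["hidden_layer_sizes"]) <= 6


class TestRegressor:
    def test_constant_target_predicts_mean(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (40, 16)).astype(np.uint8)
        reg = PChEMBLRegressor(n_estimators=(50, 100), n_trials=1,
                               random_state=0).fit(X, np.full(40, 6.0))
        assert np.allclose(reg.predict(X), 6.0, atol=1e-3)

    def test_constant_features_warn_and_fit_mean(self):
        X = np.ones((20, 8), dtype=np.uint8)
        y = np.linspace(4, 8, 20)
        with pytest.warns(UserWarning, match="constant"):
            reg = PChEMBLRegressor(n_estimators=(50, 100), n_trials=1,
                                   random_state=0).fit(X, y)
        assert np.allclose(reg.predict(X), y.mean(), atol=1e-6)

    def test_planted_single_bit_recovery(self):
        """y = 5 + 3*bit_k + noise: near-Bayes RMSE and bit k at rank 1."""
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (400, 64)).astype(np.uint8)
        k = 17
        y = 5.0 + 3.0 * X[:, k] + rng.normal(0, 0.1, 400)
        reg = PChEMBLRegressor(n_estimators=(50, 500), n_trials=3,
                               random_state=0).fit(X[:300], y[:300])
        rmse = np.sqrt(np.mean((reg.predict(X[300:]) - y[300:]) ** 2))
        assert rmse <= 0.3
        assert gain_importance(reg)[0][0] == k

    def test_partial_dependence_recovers_effect_size(self):
        """The fitted bit effect matches the planted beta within 20%."""
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (1000, 32)).astype(np.uint8)
        k, beta = 7, 3.0
        y = 5.0 + beta * X[:, k] + rng.normal(0, 0.1, 1000)
        reg = PChEMBLRegressor(n_estimators=(50, 500), n_trials=3,
                               random_state=0).fit(X, y)
        on, off = X.copy(), X.copy()
        on[:, k], off[:, k] = 1, 0
        effect = float(np.mean(reg.predict(on) - reg.predict(off)))
        assert effect == pytest.approx(beta, rel=0.2)

    def test_seeded_reproducibility(self, sar_features):
        X, y = sar_features
        kwargs = dict(n_estimators=(50, 300), n_trials=2, random_state=4)
        a = PChEMBLRegressor(**kwargs).fit(X, y)
        b = PChEMBLRegressor(**kwargs).fit(X, y)
        assert a.best_params_ == b.best_params_
        assert np.allclose(a.predict(X), b.predict(X))

    def test_wrapper_returns_triple(self, sar_features):
        X, y = sar_features
        space = RegressorSearchSpace(n_estimators=(50, 200), n_trials=1)
        predictor, cv, params = train_regressor(X, y, space)
        assert len(cv) == 10
        assert 50 <= params["n_estimators"] <= 200


class TestGainImportance:
    def test_gains_nonincreasing_and_positive(self, fitted_regressor):
        ranked = gain_importance(fitted_regressor)
        gains = [g for _, g in ranked]
        assert all(g > 0 for g in gains)
        assert gains == sorted(gains, reverse=True)

    def test_constant_model_empty(self):
        X = np.random.default_rng(0).integers(0, 2, (30, 8)).astype(np.uint8)
        reg = PChEMBLRegressor(n_estimators=(50, 100), n_trials=1,
                               random_state=0).fit(X, np.full(30, 6.0))
        assert gain_importance(reg) == []

    def test_top_k_no_padding(self, fitted_regressor):
        full = gain_importance(fitted_regressor)
        assert len(gain_importance(fitted_regressor, top_k=10 ** 6)) == \
            len(full)

    def test_non_tree_predictor_unsupported(self, fitted_classifier):
        with pytest.raises(UnsupportedModelError):
            gain_importance(fitted_classifier)


class TestImportanceReport:
    def test_planted_pharmacophore_surfaces_in_top_fragment(
            self, fitted_regressor, sar_library, sar_small, spec512):
        """The rank-1 gain bit decodes to a carrier-only substructure."""
        compounds, _ = sar_library
        report = importance_report(fitted_regressor, compounds, spec512,
                                   top_k=3)
        assert report[0].rank == 1
        assert report[0].fragment_smiles != "unresolved"
        X = featurize_set(compounds, spec512)
        carriers = X[:sar_small.n_actives, report[0].bit]
        others = X[sar_small.n_actives:, report[0].bit]
        assert carriers.mean() == 1.0
        assert others.mean() == 0.0

    def test_ranks_contiguous(self, fitted_regressor, sar_library, spec512):
        compounds, _ = sar_library
        report = importance_report(fitted_regressor, compounds, spec512,
                                   top_k=5)
        assert [r.rank for r in report] == list(range(1, len(report) + 1))

    def test_empty_records_unresolved(self, fitted_regressor, spec512):
        report = importance_report(fitted_regressor, [], spec512, top_k=2)
        assert all(r.fragment_smiles == "unresolved" for r in report)


class TestBundle:
    def test_roundtrip_and_profile_leg(self, tmp_path, fitted_regressor,
                                       sar_features, spec512, sar_library):
        from gpcrscreen.curation import assign_class

        X, y = sar_features
        y_cls = np.array([assign_class(v).label for v in y])
        clf = ActivityClassifier(**SMALL_CLF).fit(X, y_cls)
        bundle = TrainedModelBundle(
            receptor_id="CCR6", site_mode=SiteMode.ORTHOSTERIC,
            classifier=clf, regressor=fitted_regressor,
            cv_metrics={"classifier_accuracy": clf.cv_scores_,
                        "regressor_rmse": fitted_regressor.cv_scores_},
            best_hyperparameters={}, spec=spec512, seed=1)
        bundle.save(tmp_path / "b")
        loaded = TrainedModelBundle.load(tmp_path / "b")
        assert loaded.receptor_id == "CCR6"
        assert loaded.class_scheme == DEFAULT_CLASS_SCHEME

        record = sar_library[0][0]
        probs1, p1 = predict_profile_leg(bundle, record)
        probs2, p2 = predict_profile_leg(loaded, record)
        assert np.allclose(probs1, probs2)
        assert p1 == pytest.approx(p2)
        assert probs1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_spec_mismatch_is_configuration_error(self, fitted_regressor,
                                                  sar_features, sar_library):
        X, y = sar_features
        y_cls = (y > 6).astype(int)
        clf = ActivityClassifier(**SMALL_CLF).fit(X, y_cls)
        bundle = TrainedModelBundle(
            receptor_id="CCR6", site_mode=SiteMode.ORTHOSTERIC,
            classifier=clf, regressor=fitted_regressor,
            cv_metrics={}, best_hyperparameters={},
            spec=FingerprintSpec(n_bits=1024), seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            predict_profile_leg(bundle, sar_library[0][0])
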