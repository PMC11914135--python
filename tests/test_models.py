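"""Classifier fits, likelihood conventions, and the CV harness."""

import numpy as np
import pytest

from eegparity import (
    ModelHyperparams,
    airm_mean,
    cross_validate,
    fit_logistic,
    fit_model,
    fit_prk,
    fit_rlda,
    load_model,
    predict_likelihoods,
    save_model,
    tangent_vectors,
)
from eegparity.metrics import ConfusionMatrix, balanced_accuracy
from eegparity.models import _GaussianKde1D, MODEL_KINDS, _subset
from conftest import make_separable_dataset


@pytest.fixture(scope="module")
def separable():
    return make_separable_dataset()


@pytest.fixture(scope="module")
def hp():
    return ModelHyperparams()


class TestSeparableCase:
    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_training_ba_is_one(self, kind, separable, hp):
        model = fit_model(kind, separable, hp, seed=0)
        lik = predict_likelihoods(model, separable)
        cm = ConfusionMatrix.from_predictions(separable.labels, lik > 1.0)
        assert balanced_accuracy(cm) == 1.0

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_cv_perfect(self, kind, separable, hp):
        res = cross_validate(kind, separable, hp, seed=0)
        assert res.ba == 1.0
        assert res.mcc == 1.0

    def test_likelihood_direction(self, separable, hp):
        model = fit_prk(separable, hp, seed=0)
        target = separable.trials[separable.labels == 1][:1]
        nontarget = separable.trials[separable.labels == 0][:1]
        assert predict_likelihoods(model, target)[0] > 1.0
        assert predict_likelihoods(model, nontarget)[0] < 1.0


class TestNullCase:
    def test_permuted_labels_give_chance_mcc(self, hp):
        data = make_separable_dataset(n_targets=50, n_nontargets=450,
                                      amp=0.0, noise_sd=1.0, seed=3)
        res = cross_validate("PRK", data, hp, seed=3)
        assert -0.15 <= res.mcc <= 0.15


class TestPrkInternals:
    def test_degenerate_rda_is_distance_to_mean(self):
        # lambda=1, gamma=1: both covariances collapse to the same scaled
        # identity, so the score is the difference of squared distances
        data = make_separable_dataset(noise_sd=0.5, seed=1)
        hp1 = ModelHyperparams()
        hp1.prk.rda_lambda = 1.0
        hp1.prk.rda_gamma = 1.0
        model = fit_prk(data, hp1, seed=0)
        c0, _ = model.cho_factors[0]
        c1, _ = model.cho_factors[1]
        assert np.allclose(c0, c1)
        assert np.allclose(c0, c0[0, 0] * np.eye(c0.shape[0]))
        x = model._features(data.trials)
        sigma2 = c0[0, 0] ** 2
        expected = (np.sum((x - model.means[0]) ** 2, axis=1)
                    - np.sum((x - model.means[1]) ** 2, axis=1)) / (2 * sigma2)
        assert np.allclose(model.discriminant_scores(data.trials), expected,
                           atol=1e-8)

    def test_kde_integrates_to_one(self):
        rng = np.random.default_rng(0)
        kde = _GaussianKde1D(rng.normal(size=200))
        lo = kde.points.min() - 6 * kde.bandwidth
        hi = kde.points.max() + 6 * kde.bandwidth
        grid = np.linspace(lo, hi, 4001)
        integral = np.trapezoid(kde(grid), grid)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_feature_blocks_are_per_channel(self, hp):
        data = make_separable_dataset(noise_sd=0.5, seed=2)
        model = fit_prk(data, hp, seed=0)
        per_channel = [p.n_components_ for p in model.channel_pcas]
        assert model.means[0].size == sum(per_channel)
        smaller = make_separable_dataset(noise_sd=0.5, seed=2, n_ch=3)
        model3 = fit_prk(smaller, hp, seed=0)
        assert len(model3.channel_pcas) == 3

    def test_single_class_rejected(self, hp):
        data = make_separable_dataset(noise_sd=0.5, seed=1)
        data.labels[:] = 0
        with pytest.raises(ValueError):
            fit_prk(data, hp, seed=0)


class TestLogistic:
    def test_all_zero_trials_predict_class_prior(self, hp):
        data = make_separable_dataset(amp=0.0, noise_sd=0.0, seed=1)
        model = fit_logistic(data, hp, seed=0)
        x = data.trials.reshape(data.n_trials, -1)
        probs = model.pipeline.predict_proba(x)[:, 1]
        prior = data.labels.mean()
        assert np.allclose(probs, prior, atol=1e-6)
        # prior-corrected likelihood ratio sits exactly on the boundary
        assert np.allclose(predict_likelihoods(model, data), 1.0, atol=1e-6)

    def test_scale_invariance_through_standardization(self, hp):
        data = make_separable_dataset(noise_sd=0.5, seed=4)
        doubled = make_separable_dataset(noise_sd=0.5, seed=4)
        doubled.trials = 2.0 * doubled.trials
        a = predict_likelihoods(fit_logistic(data, hp, 0), data)
        b = predict_likelihoods(fit_logistic(doubled, hp, 0), doubled)
        assert np.allclose(a, b, rtol=1e-4)


class TestRiemannianGeometry:
    def test_tangent_map_of_reference_is_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5))
        m = a @ a.T + 5 * np.eye(5)
        assert np.allclose(tangent_vectors(m, m), 0.0, atol=1e-10)

    def test_mean_of_identical_matrices_is_idempotent(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        m = a @ a.T + 4 * np.eye(4)
        assert np.allclose(airm_mean(np.stack([m, m])), m, atol=1e-8)

    def test_mean_of_commuting_matrices_is_geometric(self):
        a = np.diag([1.0, 4.0, 9.0])
        b = np.diag([4.0, 1.0, 1.0])
        expected = np.diag(np.sqrt(np.diag(a) * np.diag(b)))
        assert np.allclose(airm_mean(np.stack([a, b])), expected, atol=1e-8)

    def test_tangent_dimension(self):
        rng = np.random.default_rng(2)
        mats = np.stack([np.eye(6) + 0.1 * np.diag(rng.random(6))
                         for _ in range(3)])
        vecs = tangent_vectors(mats, np.eye(6))
        assert vecs.shape == (3, 6 * 7 // 2)

    def test_rlda_fit_predict_shapes(self, separable, hp):
        model = fit_rlda(separable, hp, seed=0)
        lik = predict_likelihoods(model, separable)
        assert lik.shape == (separable.n_trials,)
        assert np.all(np.isfinite(lik)) and np.all(lik > 0)


class TestContracts:
    def test_shape_mismatch_names_expected(self, separable, hp):
        model = fit_prk(separable, hp, seed=0)
        with pytest.raises(ValueError, match="expected trials of shape"):
            predict_likelihoods(model, np.zeros((2, 3, 3)))

    def test_unknown_kind(self, separable, hp):
        with pytest.raises(ValueError):
            fit_model("SVM", separable, hp, seed=0)

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_likelihoods_finite_positive(self, kind, noisy_of_dataset, hp):
        model = fit_model(kind, noisy_of_dataset, hp, seed=0)
        lik = predict_likelihoods(model, noisy_of_dataset)
        assert np.all(np.isfinite(lik))
        assert np.all(lik > 0)

    def test_cv_deterministic(self, noisy_of_dataset, hp):
        a = cross_validate("PRK", noisy_of_dataset, hp, seed=5)
        b = cross_validate("PRK", noisy_of_dataset, hp, seed=5)
        assert np.array_equal(a.fold_ba, b.fold_ba)
        assert np.array_equal(a.fold_mcc, b.fold_mcc)
        assert a.ba == b.ba and a.mcc == b.mcc

    def test_cv_matches_manual_thresholding(self, noisy_of_dataset, hp):
        # the classifications inside cross_validate are exactly
        # "likelihood ratio > 1.0" on the held-out folds
        from sklearn.model_selection import StratifiedKFold
        from eegparity.metrics import matthews_cc
        seed = 5
        res = cross_validate("LR", noisy_of_dataset, hp, seed=seed)
        skf = StratifiedKFold(n_splits=hp.cv_folds, shuffle=True,
                              random_state=seed)
        fold_ba = []
        for tr, te in skf.split(noisy_of_dataset.trials,
                                noisy_of_dataset.labels):
            model = fit_model("LR", _subset(noisy_of_dataset, tr), hp, seed)
            lik = predict_likelihoods(model, noisy_of_dataset.trials[te])
            cm = ConfusionMatrix.from_predictions(
                noisy_of_dataset.labels[te], lik > 1.0)
            fold_ba.append(balanced_accuracy(cm))
        assert np.allclose(res.fold_ba, fold_ba)

    def test_grid_search_reports_chosen_point(self, hp):
        data = make_separable_dataset(noise_sd=0.5, seed=6)
        grid = [{"rda_lambda": 0.5, "rda_gamma": 0.5},
                {"rda_lambda": 1.0, "rda_gamma": 0.9}]
        res = cross_validate("PRK", data, hp, seed=0, grid=grid)
        assert res.chosen_params in grid

    def test_save_load_roundtrip(self, separable, hp, tmp_path):
        model = fit_prk(separable, hp, seed=0)
        save_model(model, tmp_path / "model.pkl")
        back = load_model(tmp_path / "model.pkl")
        assert np.allclose(predict_likelihoods(back, separable),
                           predict_likelihoods(model, separable))
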