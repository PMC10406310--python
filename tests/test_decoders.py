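"""Linear SVM affect classifiers, balanced LOOCV and ensemble decoding."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from affectdyn.decoders import (
    binarize_scores,
    ensemble_decode,
    fit_classifier,
    hyperplane_distance,
    loocv_balanced_accuracy,
)
from affectdyn.types import LinearDecoder


def _toy_classes(n_per_class=10, sep=4.0, dim=5, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=sep / 2, size=(n_per_class, dim))
    neg = rng.normal(loc=-sep / 2, size=(n_per_class, dim))
    X = np.vstack([pos, neg])
    scores = np.r_[np.full(n_per_class, 8.0), np.full(n_per_class, 2.0)]
    return X, binarize_scores(scores)


class TestBinarize:
    def test_scores_split_at_midpoint(self):
        out = binarize_scores([7.2, 3.1])
        np.testing.assert_array_equal(out.labels, [1, -1])

    def test_midpoint_goes_to_negative_class(self):
        assert binarize_scores([5.0]).labels[0] == -1

    def test_all_above_midpoint(self):
        assert (binarize_scores([6.0, 8.5, 5.1]).labels == 1).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_scores([0.5])


class TestFitClassifier:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        X, labels = _toy_classes()
        model = fit_classifier(X, labels)
        preds = np.where(model.predict(X) > 0, 1, -1)
        np.testing.assert_array_equal(preds, labels.labels)

    def test_label_flip_negates_hyperplane(self):
        X, labels = _toy_classes()
        m1 = fit_classifier(X, labels)
        flipped = binarize_scores(10.0 - labels.source_scores)
        m2 = fit_classifier(X, flipped)
        # agreement is limited by the solver's solution tolerance (1e-3)
        np.testing.assert_allclose(m1.weights, -m2.weights, atol=1e-3)
        assert m1.offset == pytest.approx(-m2.offset, abs=1e-3)

    def test_duplicating_samples_keeps_hyperplane(self):
        X, labels = _toy_classes()
        m1 = fit_classifier(X, labels)
        m2 = fit_classifier(
            np.vstack([X, X]), binarize_scores(np.tile(labels.source_scores, 2))
        )
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-4)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_classifier(X, binarize_scores(np.full(6, 8.0)))


class TestHyperplaneDistance:
    def test_point_on_hyperplane_is_zero(self):
        m = LinearDecoder(
            weights=[1.0, 1.0], offset=-2.0, target=("valence", 0),
            model_form="classifier",
        )
        assert hyperplane_distance(m, [1.0, 1.0]) == pytest.approx(0.0)

    def test_hand_checkable_geometry(self):
        m = LinearDecoder(
            weights=[3.0, 4.0], offset=0.0, target=("valence", 0),
            model_form="classifier",
        )
        assert hyperplane_distance(m, [3.0, 4.0]) == pytest.approx(5.0)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=2))
    def test_sign_matches_predicted_class(self, x):
        m = LinearDecoder(
            weights=[1.5, -2.0], offset=0.3, target=("valence", 0),
            model_form="classifier",
        )
        d = hyperplane_distance(m, x)
        raw = 1.5 * x[0] - 2.0 * x[1] + 0.3
        assert np.sign(d) == np.sign(raw)

    def test_zero_norm_weights_rejected(self):
        m = LinearDecoder(
            weights=[0.0, 0.0], offset=0.0, target=("valence", 0),
            model_form="classifier",
        )
        with pytest.raises(ValueError, match="zero-norm"):
            hyperplane_distance(m, [1.0, 2.0])


class TestBalancedLoocv:
    def test_separable_data_near_perfect(self):
        X, labels = _toy_classes(n_per_class=12, sep=6.0)
        cv = loocv_balanced_accuracy(X, labels, n_resamples=5, seed=0)
        assert cv.accuracy > 0.95
        assert cv.null_rate == 0.5

    def test_permuted_labels_stay_at_chance(self):
        rng = np.random.default_rng(3)
        X, labels = _toy_classes(n_per_class=12, sep=6.0)
        permuted = binarize_scores(rng.permutation(labels.source_scores))
        cv = loocv_balanced_accuracy(X, permuted, n_resamples=10, seed=1)
        n = np.prod(cv.fold_predictions.shape)
        band = 1.96 * np.sqrt(0.25 / cv.fold_predictions.shape[0])
        assert abs(cv.accuracy - 0.5) < band + 0.1  # fold-level binomial band

    def test_single_resample_is_deterministic(self):
        X, labels = _toy_classes(n_per_class=6)
        a = loocv_balanced_accuracy(X, labels, n_resamples=1, seed=9)
        b = loocv_balanced_accuracy(X, labels, n_resamples=1, seed=9)
        assert a.accuracy == b.accuracy
        np.testing.assert_array_equal(a.fold_predictions, b.fold_predictions)

    def test_lone_class_member_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        labels = binarize_scores([8.0, 2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            loocv_balanced_accuracy(X, labels, n_resamples=2, seed=0)


def _const_model(d, w=(1.0,)):
    """Classifier whose distance for x=[d] is d (unit weight, zero offset)."""
    return LinearDecoder(
        weights=list(w), offset=0.0, target=("valence", 0), model_form="classifier"
    )


class TestEnsembleDecode:
    def test_mean_of_two_distances(self):
        models = [
            LinearDecoder([1.0], 0.4 - 1.0, ("valence", 0), "classifier"),
            LinearDecoder([1.0], -0.2 - 1.0, ("valence", 0), "classifier"),
        ]
        mean, _ = ensemble_decode(models, np.array([1.0]))
        assert mean == pytest.approx(0.1)

    def test_identical_models_zero_width_ci(self):
        m = LinearDecoder([2.0], 0.5, ("valence", 0), "classifier")
        mean, (lo, hi) = ensemble_decode([m, m, m], np.array([1.0]))
        assert lo == hi == mean

    def test_ci_contains_mean_and_is_symmetric(self):
        models = [
            LinearDecoder([1.0], b, ("valence", 0), "classifier")
            for b in (-0.5, 0.1, 0.7)
        ]
        mean, (lo, hi) = ensemble_decode(models, np.array([0.0]))
        assert lo <= mean <= hi
        assert (mean - lo) == pytest.approx(hi - mean)

    def test_mixed_targets_rejected(self):
        a = LinearDecoder([1.0], 0.0, ("valence", 0), "classifier")
        b = LinearDecoder([1.0], 0.0, ("arousal", 0), "classifier")
        with pytest.raises(ValueError, match="mixed"):
            ensemble_decode([a, b], np.array([1.0]))

    @given(st.floats(-3, 3))
    def test_adding_a_model_moves_mean_toward_its_distance(self, d):
        base = [
            LinearDecoder([1.0], b, ("valence", 0), "classifier")
            for b in (0.2, -0.4, 0.9)
        ]
        x = np.array([0.0])
        mean0, _ = ensemble_decode(base, x)
        extra = LinearDecoder([1.0], d, ("valence", 0), "classifier")
        mean1, _ = ensemble_decode(base + [extra], x)
        if d > mean0:
            assert mean0 <= mean1 <= d
        else:
            assert d <= mean1 <= mean0
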