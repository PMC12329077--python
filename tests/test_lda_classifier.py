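import numpy as np
import pytest

from pclda.io_formats import PredictionTable
from pclda.lda_classifier import (
    LDAModel,
    apply_unknown_threshold,
    confidence_scores,
    decision_function,
    fit_discriminants,
    fit_lda_projection,
    predict,
)

from conftest import make_labels


def one_d_model(means=(0.0, 2.0), sigma=1.0, priors=(0.5, 0.5)):
    """Hand-built 1-D LDA-space model with explicit parameters."""
    means = np.asarray(means, float)[:, None]
    sigma_w = np.array([[sigma]])
    coef = means / sigma
    intercept = -0.5 * (means**2 / sigma).ravel() + np.log(priors)
    return LDAModel(
        W=np.eye(1),
        classes=np.array(["c1", "c2"], object),
        class_means_lda=means,
        sigma_w=sigma_w,
        priors=np.asarray(priors, float),
        coef=coef,
        intercept=intercept,
    )


class TestProjection:
    def test_axis_aligned_two_class(self, rng):
        # identity within-scatter, mean difference along axis 0
        z = np.vstack([
            rng.normal([0, 0], 1.0, size=(40, 2)),
            rng.normal([6, 0], 1.0, size=(40, 2)),
        ])
        labels = make_labels(["A"] * 40 + ["B"] * 40)
        W, _ = fit_lda_projection(z, labels)
        assert abs(W[0, 0]) == pytest.approx(1.0, abs=0.05)
        assert np.linalg.norm(W[:, 0]) == pytest.approx(1.0, abs=1e-10)

    def test_beats_random_projections(self, gaussian_classes, rng):
        """Fitted W's between/within trace ratio tops 1000 random projections."""
        z, labels = gaussian_classes
        W, _ = fit_lda_projection(z, labels)

        def trace_ratio(proj):
            from pclda.lda_classifier import _scatter_matrices

            S_B, S_W = _scatter_matrices(z @ proj, labels, diagonal=False)
            return np.trace(S_B) / np.trace(S_W)

        fitted = trace_ratio(W)
        randoms = []
        for _ in range(1000):
            R = rng.normal(size=W.shape)
            R /= np.linalg.norm(R, axis=0)
            randoms.append(trace_ratio(R))
        assert fitted >= max(randoms)

    def test_separation_invariant_under_invertible_map(self, gaussian_classes):
        """Mapping inputs by A and W by inv(A).T leaves projections unchanged."""
        z, labels = gaussian_classes
        W, _ = fit_lda_projection(z, labels)
        A = np.array([[2.0, 0.3, 0, 0, 0],
                      [0.1, 1.5, 0, 0, 0],
                      [0, 0, 1.0, 0.2, 0],
                      [0, 0, 0, 0.8, 0],
                      [0.5, 0, 0, 0, 1.2]])
        np.testing.assert_allclose((z @ A.T) @ (np.linalg.inv(A).T @ W), z @ W, atol=1e-8)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_lda_projection(np.ones((4, 2)), make_labels(["A"] * 4))

    def test_d_below_c_minus_1_warns(self, rng):
        z = rng.normal(size=(30, 1))
        z[:10] += 5
        z[10:20] -= 5
        labels = make_labels(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        with pytest.warns(UserWarning, match="discriminant axes"):
            W, _ = fit_lda_projection(z, labels)
        assert W.shape == (1, 1)

    def test_diagonal_scatter_yields_axis_vectors(self, rng):
        """The per-coordinate scatter mode reduces to picking single PCs."""
        z = rng.normal(size=(60, 4))
        z[:30, 2] += 4  # only coordinate 2 separates
        labels = make_labels(["A"] * 30 + ["B"] * 30)
        W, _ = fit_lda_projection(z, labels, scatter="diagonal")
        assert np.abs(W[2, 0]) == pytest.approx(1.0, abs=1e-8)


class TestDiscriminants:
    def test_symmetric_classes_equal_intercepts(self):
        z = np.array([[-2.0], [-1.0], [-3.0], [2.0], [1.0], [3.0]])
        labels = make_labels(["A"] * 3 + ["B"] * 3)
        model = fit_discriminants(z, labels)
        assert model.intercept[0] == pytest.approx(model.intercept[1], abs=1e-12)

    def test_one_dimensional_delta_difference(self):
        # means 0 and 2, sigma 1, equal priors: delta_2 - delta_1 at z=1.5 is 1
        model = one_d_model()
        delta = decision_function(np.array([[1.5]]), model)
        assert delta[0, 1] - delta[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_priors_from_counts(self):
        z = np.array([[0.1], [0.2], [0.0], [5.0]])
        labels = make_labels(["A", "A", "A", "B"])
        model = fit_discriminants(z, labels)
        np.testing.assert_allclose(model.priors, [0.75, 0.25])

    def test_sigma_w_pooled_scaling(self, rng):
        z = rng.normal(size=(20, 2))
        labels = make_labels(["A"] * 10 + ["B"] * 10)
        model = fit_discriminants(z, labels)
        expected = np.zeros((2, 2))
        for c in "AB":
            r = z[labels.labels == c] - z[labels.labels == c].mean(0)
            expected += r.T @ r
        np.testing.assert_allclose(model.sigma_w, expected / (20 - 2), atol=1e-12)

    def test_discriminants_recomputable_from_stored_parts(self, rng):
        z = rng.normal(size=(30, 3))
        z[:15] += [3, 0, 0]
        labels = make_labels(["A"] * 15 + ["B"] * 15)
        model = fit_discriminants(z, labels)
        for ci in range(2):
            w = np.linalg.solve(model.sigma_w, model.class_means_lda[ci])
            b = -0.5 * model.class_means_lda[ci] @ w + np.log(model.priors[ci])
            np.testing.assert_allclose(model.coef[ci], w, atol=1e-10)
            assert model.intercept[ci] == pytest.approx(b, abs=1e-10)

    def test_too_few_cells_errors(self):
        z = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError, match="more cells than classes"):
            fit_discriminants(z, make_labels(["A", "B"]))


class TestPrediction:
    def test_two_class_posterior_closed_form(self):
        model = one_d_model()
        pred = predict(np.array([[1.5]]), model)
        assert pred.predicted_labels[0] == "c2"
        assert pred.posteriors[0, 1] == pytest.approx(np.e / (1 + np.e), abs=1e-12)

    def test_midpoint_tie_goes_to_first_class(self):
        model = one_d_model()
        pred = predict(np.array([[1.0]]), model)
        np.testing.assert_allclose(pred.posteriors[0], [0.5, 0.5], atol=1e-12)
        assert pred.predicted_labels[0] == "c1"

    def test_far_training_cell_recovers_own_class(self, rng):
        z = np.vstack([rng.normal(0, 1, (20, 2)), rng.normal(30, 1, (20, 2))])
        labels = make_labels(["A"] * 20 + ["B"] * 20)
        model = fit_discriminants(z, labels)
        pred = predict(z, model)
        assert list(pred.predicted_labels) == list(labels.labels)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError, match="does not match"):
            predict(np.ones((2, 3)), one_d_model())

    def test_matches_brute_force_gaussian_classifier(self, gaussian_classes):
        """Predictions equal a direct shared-covariance Gaussian argmax."""
        z, labels = gaussian_classes
        W, ridge = fit_lda_projection(z, labels)
        model = fit_discriminants(z @ W, labels, W=W, scatter_ridge=ridge)
        pred = predict(z, model)
        z_lda = z @ W
        inv = np.linalg.inv(model.sigma_w)
        expected = []
        for i in range(len(z_lda)):
            scores = [
                -0.5 * (z_lda[i] - model.class_means_lda[c]) @ inv
                @ (z_lda[i] - model.class_means_lda[c]) + np.log(model.priors[c])
                for c in range(3)
            ]
            expected.append(model.classes[int(np.argmax(scores))])
        assert list(pred.predicted_labels) == expected

    def test_matches_sklearn_lda_labels(self, gaussian_classes):
        """Cross-check against scikit-learn's LDA on the projected scores."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        z, labels = gaussian_classes
        W, ridge = fit_lda_projection(z, labels)
        model = fit_discriminants(z @ W, labels, W=W, scatter_ridge=ridge)
        pred = predict(z, model)
        clf = sklearn.LinearDiscriminantAnalysis(solver="svd")
        clf.fit(z @ W, labels.labels.astype(str))
        assert list(pred.predicted_labels) == list(clf.predict(z @ W))

    def test_posterior_shift_invariance(self, rng):
        """Adding a constant to every delta leaves posteriors unchanged."""
        model = one_d_model()
        z = rng.normal(size=(10, 1))
        base = predict(z, model).posteriors
        shifted = LDAModel(
            model.W, model.classes, model.class_means_lda, model.sigma_w,
            model.priors, model.coef, model.intercept + 11.7,
        )
        np.testing.assert_allclose(predict(z, shifted).posteriors, base, atol=1e-12)

    def test_raising_prior_never_lowers_posterior(self):
        z = np.array([[0.7]])
        for p in (0.2, 0.4, 0.6, 0.8):
            lo = predict(z, one_d_model(priors=(1 - p, p))).posteriors[0, 1]
            hi = predict(z, one_d_model(priors=(1 - p - 0.1, p + 0.1))).posteriors[0, 1]
            assert hi >= lo

    def test_delta_affine_in_scores(self, rng):
        """delta_c(alpha * z) - delta_c(z) is linear in alpha."""
        model = one_d_model()
        z = rng.normal(size=(5, 1))
        d1 = decision_function(z, model)
        d2 = decision_function(2 * z, model)
        d3 = decision_function(3 * z, model)
        np.testing.assert_allclose(d3 - d1, 2 * (d2 - d1), atol=1e-10)


class TestConfidenceAndThreshold:
    def make_pred(self, labels, posteriors):
        posteriors = np.asarray(posteriors, float)
        return PredictionTable(
            np.array([f"c{i}" for i in range(len(labels))], object),
            np.asarray(labels, object),
            posteriors,
            np.array(["A", "B"], object),
        )

    def test_mean_winning_posterior(self):
        pred = self.make_pred(["A", "A"], [[0.8, 0.2], [0.6, 0.4]])
        conf = confidence_scores(pred)
        assert conf.values[0] == pytest.approx(0.7)

    def test_never_predicted_class_is_nan(self):
        pred = self.make_pred(["A", "A"], [[0.8, 0.2], [0.6, 0.4]])
        assert np.isnan(confidence_scores(pred).values[1])

    def test_certain_predictions_give_one(self):
        pred = self.make_pred(["A", "B"], [[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(confidence_scores(pred).values, [1.0, 1.0])

    def test_defined_confidences_at_least_uniform(self, rng):
        post = rng.dirichlet([1, 1], size=50)
        labels = np.array(["A", "B"], object)[np.argmax(post, axis=1)]
        conf = confidence_scores(self.make_pred(labels, post))
        defined = conf.values[np.isfinite(conf.values)]
        assert np.all(defined >= 0.5)

    def test_tau_zero_is_identity(self):
        pred = self.make_pred(["A", "B"], [[0.55, 0.45], [0.3, 0.7]])
        out = apply_unknown_threshold(pred, 0.0)
        assert list(out.predicted_labels) == ["A", "B"]

    def test_threshold_relabels_low_confidence(self):
        pred = self.make_pred(["A"], [[0.55, 0.45]])
        out = apply_unknown_threshold(pred, 0.6)
        assert out.predicted_labels[0] == "Unknown"
        np.testing.assert_array_equal(out.posteriors, pred.posteriors)

    def test_tau_one_rejects_all_uncertain(self):
        pred = self.make_pred(["A", "B"], [[0.9, 0.1], [0.0, 1.0]])
        out = apply_unknown_threshold(pred, 1.0)
        assert list(out.predicted_labels) == ["Unknown", "B"]

    def test_tau_out_of_range_rejected(self):
        pred = self.make_pred(["A"], [[0.9, 0.1]])
        with pytest.raises(ValueError):
            apply_unknown_threshold(pred, 1.0 + 1e-9)
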