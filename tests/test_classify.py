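"""Discriminant classifiers, PLS-DA, KNN, SVM and cross-validation."""

import numpy as np
import pytest

from salivaspec.classify import (
    cross_validate,
    fit_discriminant,
    fit_knn,
    fit_plsda,
    fit_svm,
    predict_discriminant,
    predict_knn,
    predict_plsda,
    predict_svm,
)


def _two_gaussians(rng, n_per, dim, shift, scale_pos=1.0):
    pos = rng.normal(size=(n_per, dim)) * scale_pos + shift
    ctl = rng.normal(size=(n_per, dim))
    X = np.vstack([pos, ctl])
    labels = np.array(["positive"] * n_per + ["control"] * n_per)
    return X, labels


class TestDiscriminant:
    def test_linear_boundary_at_midpoint_1d(self):
        rng = np.random.default_rng(0)
        n = 100_000
        X = np.concatenate([rng.normal(2.0, 1.0, n), rng.normal(0.0, 1.0, n)])
        labels = np.array(["positive"] * n + ["control"] * n)
        model = fit_discriminant(X[:, None], labels, kind="linear")
        grid = np.linspace(0.2, 1.8, 2001)[:, None]
        pred = predict_discriminant(model, grid).predicted
        boundary = grid[np.argmax(pred == "positive")][0]
        assert boundary == pytest.approx(1.0, abs=0.02)

    def test_quadratic_reduces_to_linear_with_equal_covariances(self):
        rng = np.random.default_rng(1)
        X, labels = _two_gaussians(rng, 60, 3, shift=1.5)
        lda = fit_discriminant(X, labels, kind="linear")
        qda = fit_discriminant(X, labels, kind="quadratic")
        # force the per-class covariances equal to the pooled one
        pooled = lda.covariances["pooled"]
        for c in qda.class_labels:
            qda.covariances[c] = pooled
            qda.inverses[c] = np.linalg.inv(pooled)
            qda.logdets[c] = float(np.linalg.slogdet(pooled)[1])
        grid = rng.normal(size=(500, 3)) * 2
        assert np.array_equal(
            predict_discriminant(qda, grid).predicted,
            predict_discriminant(lda, grid).predicted,
        )

    def test_qda_matches_gaussian_log_density_oracle(self):
        rng = np.random.default_rng(2)
        X, labels = _two_gaussians(rng, 80, 3, shift=1.0, scale_pos=0.5)
        model = fit_discriminant(X, labels, kind="quadratic", priors="proportional")
        pts = rng.normal(size=(2000, 3)) * 1.5
        pred = predict_discriminant(model, pts).predicted

        from scipy.stats import multivariate_normal

        logp = {}
        for c in model.class_labels:
            mvn = multivariate_normal(model.means[c], model.covariances[c])
            logp[c] = mvn.logpdf(pts) + np.log(model.priors[c])
        oracle = np.where(logp["positive"] > logp["control"], "positive", "control")
        assert np.mean(pred != oracle) <= 1e-10

    def test_point_at_positive_mean_is_positive(self):
        rng = np.random.default_rng(3)
        X, labels = _two_gaussians(rng, 50, 2, shift=5.0)
        model = fit_discriminant(X, labels, kind="quadratic")
        out = predict_discriminant(model, model.means["positive"][None, :])
        assert out.predicted[0] == "positive"

    def test_tie_breaks_toward_control(self):
        # perfectly symmetric classes: the midpoint is an exact tie
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        labels = np.array(["positive", "positive", "control", "control"])
        model = fit_discriminant(X, labels, kind="linear")
        out = predict_discriminant(model, np.array([[0.0]]))
        assert out.decision_score[0] == pytest.approx(0.0, abs=1e-12)
        assert out.predicted[0] == "control"

    def test_decision_score_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(4)
        X, labels = _two_gaussians(rng, 40, 2, shift=1.0)
        pts = rng.normal(size=(50, 2))
        a = predict_discriminant(fit_discriminant(X, labels, kind="quadratic"), pts)
        swapped = np.where(labels == "positive", "control", "positive")
        b = predict_discriminant(fit_discriminant(X, swapped, kind="quadratic"), pts)
        assert np.allclose(a.decision_score, -b.decision_score, atol=1e-10)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_discriminant(X, np.array(["positive", "control", "control"]))

    def test_singular_covariance_regularised(self):
        # 8 features, 5 samples per class: raw covariance is singular
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 8))
        labels = np.array(["positive"] * 5 + ["control"] * 5)
        model = fit_discriminant(X, labels, kind="quadratic")
        out = predict_discriminant(model, X)
        assert np.isfinite(out.decision_score).all()


class TestPLSDA:
    def test_separable_training_data_classified_perfectly(self):
        rng = np.random.default_rng(6)
        X, labels = _two_gaussians(rng, 40, 10, shift=4.0)
        model = fit_plsda(X, labels, a=2)
        pred = predict_plsda(model, X).predicted
        assert np.array_equal(pred, labels)

    def test_one_lv_equals_lda_on_first_score(self):
        rng = np.random.default_rng(7)
        X, labels = _two_gaussians(rng, 30, 6, shift=2.0)
        model = fit_plsda(X, labels, a=1)
        scores = (X - model.pls.x_mean) @ model.pls._sk.x_rotations_
        lda = fit_discriminant(scores, labels, kind="linear")
        assert np.array_equal(
            predict_plsda(model, X).predicted,
            predict_discriminant(lda, scores).predicted,
        )

    def test_cv_choice_of_lv_count_is_deterministic(self):
        rng = np.random.default_rng(8)
        X, labels = _two_gaussians(rng, 25, 8, shift=1.5)
        a1 = fit_plsda(X, labels, seed=3).a
        a2 = fit_plsda(X, labels, seed=3).a
        assert a1 == a2


class TestKNN:
    def test_k1_returns_training_label(self):
        rng = np.random.default_rng(9)
        X, labels = _two_gaussians(rng, 20, 2, shift=3.0)
        model = fit_knn(X, labels, k=1)
        assert np.array_equal(predict_knn(model, X).predicted, labels)

    def test_k_equals_n_train_returns_majority(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 2))
        labels = np.array(["control"] * 20 + ["positive"] * 10)
        model = fit_knn(X, labels, k=30)
        pred = predict_knn(model, rng.normal(size=(15, 2)) * 5).predicted
        assert np.all(pred == "control")

    def test_matches_exhaustive_vote_oracle(self):
        rng = np.random.default_rng(11)
        X, labels = _two_gaussians(rng, 25, 2, shift=1.0)
        pts = rng.normal(size=(40, 2))
        k = 5
        model = fit_knn(X, labels, k=k)
        pred = predict_knn(model, pts).predicted
        for i, p in enumerate(pts):
            d = np.linalg.norm(X - p, axis=1)
            votes = labels[np.argsort(d, kind="stable")[:k]]
            majority = "positive" if np.sum(votes == "positive") > k / 2 else "control"
            assert pred[i] == majority

    def test_k_larger_than_training_rejected(self):
        X = np.zeros((4, 2))
        labels = np.array(["positive", "positive", "control", "control"])
        with pytest.raises(ValueError):
            fit_knn(X, labels, k=9)


class TestSVM:
    def test_separable_data_zero_training_error(self):
        rng = np.random.default_rng(12)
        X, labels = _two_gaussians(rng, 30, 2, shift=6.0)
        model = fit_svm(X, labels, kernel="linear", params={"cost": 1.0})
        assert np.array_equal(predict_svm(model, X).predicted, labels)

    def test_xor_needs_a_nonlinear_kernel(self):
        rng = np.random.default_rng(13)
        n = 50
        centres = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float) * 2
        X = np.vstack([c + 0.3 * rng.normal(size=(n, 2)) for c in centres])
        labels = np.array(["positive"] * (2 * n) + ["control"] * (2 * n))

        def cv_acc(kernel):
            model_fit = lambda X, y, cost: fit_svm(
                X, y, kernel=kernel, params={"cost": cost}
            )
            res = cross_validate(
                model_fit, predict_svm, [{"cost": 1.0}], X, labels, folds=5, seed=0
            )
            return res["best_accuracy"]

        assert cv_acc("linear") < 0.7
        assert cv_acc("rbf") >= 0.95

    def test_duplicating_non_support_point_changes_nothing(self):
        rng = np.random.default_rng(14)
        X, labels = _two_gaussians(rng, 30, 2, shift=8.0)
        model = fit_svm(X, labels, kernel="linear", params={"cost": 1.0})
        # farthest-from-boundary point is not a support vector
        far = np.argmax(np.abs(predict_svm(model, X).decision_score))
        X2 = np.vstack([X, X[far]])
        labels2 = np.append(labels, labels[far])
        model2 = fit_svm(X2, labels2, kernel="linear", params={"cost": 1.0})
        pts = rng.normal(size=(50, 2)) * 3
        assert np.array_equal(
            predict_svm(model, pts).predicted, predict_svm(model2, pts).predicted
        )

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            fit_svm(np.zeros((4, 2)),
                    np.array(["positive", "positive", "control", "control"]),
                    kernel="sigmoid", params={"cost": 1.0})


class TestCrossValidate:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(15)
        X, labels = _two_gaussians(rng, 20, 2, shift=2.0)
        res = cross_validate(
            lambda X, y, k: fit_knn(X, y, k=k), predict_knn,
            [{"k": 3}], X, labels, folds=5, seed=0,
        )
        assert res["best_params"] == {"k": 3}

    def test_leave_one_out_on_ten_rows(self):
        rng = np.random.default_rng(16)
        X, labels = _two_gaussians(rng, 5, 2, shift=4.0)
        res = cross_validate(
            lambda X, y, k: fit_knn(X, y, k=k), predict_knn,
            [{"k": 1}], X, labels, folds=10, seed=0,
        )
        assert len(res["cv_table"]) == 1  # ran without error at folds=n

    def test_informative_mask_beats_random_mask(self):
        rng = np.random.default_rng(17)
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            n, p = 60, 30
            labels = np.array(["positive"] * 30 + ["control"] * 30)
            X = r.normal(size=(n, p))
            informative = [2, 9, 17]
            for j in informative:
                X[:30, j] += 2.0
            fit = lambda X, y: fit_discriminant(X, y, kind="linear")

            def acc(cols):
                res = cross_validate(
                    lambda X, y: fit(X, y), predict_discriminant,
                    [{}], X[:, cols], labels, folds=5, seed=seed,
                )
                return res["best_accuracy"]

            random_cols = r.choice(
                [j for j in range(p) if j not in informative], 3, replace=False
            )
            wins += acc(informative) > acc(list(random_cols))
        assert wins >= 9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(18)
        X, labels = _two_gaussians(rng, 20, 3, shift=1.0)
        grid = [{"k": k} for k in (1, 3, 5)]
        r1 = cross_validate(lambda X, y, k: fit_knn(X, y, k=k), predict_knn,
                            grid, X, labels, folds=4, seed=7)
        r2 = cross_validate(lambda X, y, k: fit_knn(X, y, k=k), predict_knn,
                            grid, X, labels, folds=4, seed=7)
        assert r1["best_params"] == r2["best_params"]
        assert [row["mean_accuracy"] for row in r1["cv_table"]] == [
            row["mean_accuracy"] for row in r2["cv_table"]
        ]


class TestVarianceAsymmetryRationale:
    def test_qda_beats_lda_on_tight_minority_class(self):
        """Per-class covariance wraps a tight minority cluster that a pooled
        covariance smears: QDA should win on the SENS/SPEC geometric mean."""
        from salivaspec.validate import confusion, metrics

        wins = ties = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(300 + seed)
            n_pos, n_ctl = 30, 300
            X = np.vstack([
                rng.normal(size=(n_pos, 4)) * 0.4 + 1.2,
                rng.normal(size=(n_ctl, 4)) * 1.5,
            ])
            labels = np.array(["positive"] * n_pos + ["control"] * n_ctl)
            Xt = np.vstack([
                rng.normal(size=(n_pos, 4)) * 0.4 + 1.2,
                rng.normal(size=(n_ctl, 4)) * 1.5,
            ])

            def g_score(kind):
                model = fit_discriminant(X, labels, kind=kind)
                pred = predict_discriminant(model, Xt).predicted
                return metrics(confusion(labels, pred)).g

            gq, gl = g_score("quadratic"), g_score("linear")
            wins += gq > gl + 1e-12
            ties += abs(gq - gl) <= 1e-12
        assert wins + ties >= int(0.8 * n_seeds)
        assert wins >= n_seeds // 2  # the advantage is strict most of the time
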