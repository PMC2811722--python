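"""PCA, RBF-SVM (with QP/KKT oracles) and confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

import vocpanel as vp
from vocpanel.classify import ConfusionMetrics
from vocpanel.errors import DataError


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_collinear_2d_data_has_pc1_fraction_one(self):
        t = np.linspace(-2, 2, 9)
        X = np.c_[t, 3 * t + 1.0]
        model = vp.pca_fit(X, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_training_mean_projects_to_origin(self, rng):
        X = rng.normal(size=(8, 4))
        model = vp.pca_fit(X, 2)
        assert vp.pca_project(model, X.mean(axis=0)) == pytest.approx(
            np.zeros((1, 2)), abs=1e-12
        )

    def test_scores_are_decorrelated_with_eigen_variances(self, rng):
        X = rng.normal(size=(5, 3))
        model = vp.pca_fit(X)
        scores = vp.pca_project(model, X)
        gram = scores.T @ scores / (X.shape[0] - 1)
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-10)
        # diagonal equals the covariance eigenvalues, largest first
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert np.allclose(np.diag(gram), evals[: model.n_components])

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(10, 4))
        model = vp.pca_fit(X)
        scores = vp.pca_project(model, X)
        back = scores @ model.components + model.mean
        assert np.allclose(back, X, atol=1e-8)

    def test_loadings_orthonormal_and_sign_convention(self, rng):
        X = rng.normal(size=(12, 5))
        model = vp.pca_fit(X)
        C = model.components
        assert np.allclose(C @ C.T, np.eye(C.shape[0]), atol=1e-10)
        for row in C:
            assert row[np.argmax(np.abs(row))] > 0
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
        assert model.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_rank_overflow_rejected(self, rng):
        X = rng.normal(size=(3, 5))  # rank 2 after centering
        with pytest.raises(DataError):
            vp.pca_fit(X, 4)


# ---------------------------------------------------------------------------
# SVM


def dual_qp_oracle(X, y, sigma, C):
    """Independent dual solution: box+equality constrained QP.

    maximize sum(a) - 1/2 a' Q a  with  Q_ij = y_i y_j k(x_i, x_j),
    0 <= a <= C, y'a = 0.  Solved by trust-constr from several feasible
    starts, each polished by SLSQP; the best feasible value wins.
    """
    from scipy.optimize import Bounds, LinearConstraint
    from scipy.spatial.distance import cdist

    K = np.exp(-sigma * cdist(X, X, "sqeuclidean"))
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def grad(a):
        return -(np.ones(n) - Q @ a)

    eq = LinearConstraint(y.astype(float), 0.0, 0.0)
    best = -np.inf
    for frac in (0.0, 0.25, 0.5):
        x0 = np.full(n, frac * C)
        res = minimize(
            neg_obj, x0, jac=grad, method="trust-constr",
            hess=lambda a: Q,
            bounds=Bounds(0.0, C), constraints=[eq],
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000},
        )
        polish = minimize(
            neg_obj, res.x, jac=grad, method="SLSQP",
            bounds=[(0.0, C)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a @ y,
                          "jac": lambda a: y.astype(float)}],
            options={"maxiter": 2000, "ftol": 1e-16},
        )
        for cand in (res.x, polish.x):
            cand = np.clip(cand, 0.0, C)
            if abs(cand @ y) < 1e-8:
                best = max(best, -neg_obj(cand))
    assert np.isfinite(best)
    return best


def check_kkt(model, X, y, tol=1e-6):
    """Complementary-slackness conditions of the soft-margin dual."""
    dec = model.decision(X)
    margins = y * dec
    # recover alpha per training point (0 for non-support samples)
    alpha = np.zeros(len(y))
    for sv, coef in zip(model.support_vectors, model.dual_coef):
        idx = np.flatnonzero(np.all(np.isclose(X, sv, atol=1e-12), axis=1))[0]
        alpha[idx] = abs(coef)
    free = (alpha > tol) & (alpha < model.C - tol)
    assert np.all(margins[alpha <= tol] >= 1 - 1e-4)
    assert np.all(np.abs(margins[free] - 1) < 1e-4)
    assert np.all(margins[alpha >= model.C - tol] <= 1 + 1e-4)
    assert abs(np.sum(alpha * y)) < 1e-6


def best_linear_accuracy(X, y, n_angles=720):
    """Exhaustive angle sweep for the best 2-D linear separator."""
    best = 0.0
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        proj = X @ np.array([np.cos(theta), np.sin(theta)])
        order = np.argsort(proj)
        sorted_y = y[order]
        # evaluate all thresholds between consecutive projections
        for cut in range(len(y) + 1):
            pred = np.r_[-np.ones(cut), np.ones(len(y) - cut)]
            acc = max(np.mean(pred == sorted_y), np.mean(-pred == sorted_y))
            best = max(best, acc)
    return best


class TestSvm:
    def test_separated_clouds_train_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.r_[-np.ones(10), np.ones(10)]
        model = vp.svm_train(X, y, sigma=0.9, C=10.0)
        pred, _ = vp.svm_predict(model, X)
        assert np.array_equal(pred, y)

    def test_kernel_identities(self, rng):
        X = rng.normal(size=(6, 3))
        model = vp.svm_train(
            np.vstack([X, X + 5]), np.r_[-np.ones(6), np.ones(6)]
        )
        K = model.kernel(X, X)
        assert np.allclose(np.diag(K), 1.0)
        assert np.allclose(K, K.T)
        evals = np.linalg.eigvalsh(K)
        assert evals.min() > -1e-10  # PSD

    def test_xor_pattern_beats_any_linear_separator(self, rng):
        centers = np.array([[1, 1], [-1, -1], [1, -1], [-1, 1]], dtype=float)
        X = np.vstack([c + rng.normal(0, 0.15, (8, 2)) for c in centers])
        y = np.r_[np.ones(16), -np.ones(16)]
        model = vp.svm_train(X, y, sigma=0.9, C=10.0)
        pred, _ = vp.svm_predict(model, X)
        rbf_acc = np.mean(pred == y)
        assert rbf_acc == 1.0
        assert best_linear_accuracy(X, y) < 1.0

    def test_dual_objective_matches_qp_oracle(self, rng):
        """libsvm solution vs an independent SLSQP quadratic program on
        small random problems, plus the KKT conditions."""
        for trial in range(5):
            n = int(rng.integers(8, 16))
            X = rng.normal(size=(n, 2))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            y[0], y[1] = 1.0, -1.0  # both classes present
            model = vp.svm_train(X, y, sigma=0.9, C=1.0)
            oracle = dual_qp_oracle(X, y, sigma=0.9, C=1.0)
            assert model.dual_objective() == pytest.approx(
                oracle, abs=1e-6, rel=1e-6
            )
            check_kkt(model, X, y)

    def test_free_support_vector_sits_on_margin(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(20) > 0, 1.0, -1.0)
        if len(np.unique(y)) == 1:
            y[0] = -y[0]
        model = vp.svm_train(X, y, sigma=0.9, C=1.0)
        alpha = np.abs(model.dual_coef)
        free = (alpha > 1e-6) & (alpha < model.C - 1e-6)
        if free.any():
            dec_sv = model.decision(model.support_vectors[free])
            assert np.allclose(np.abs(dec_sv), 1.0, atol=1e-4)

    def test_label_swap_negates_decision(self, rng):
        X = rng.normal(size=(14, 3))
        y = np.r_[np.ones(7), -np.ones(7)]
        d1 = vp.svm_predict(vp.svm_train(X, y), X)[1]
        d2 = vp.svm_predict(vp.svm_train(X, -y), X)[1]
        assert np.allclose(d1, -d2, atol=1e-8)

    def test_empty_prediction_input(self, rng):
        X = rng.normal(size=(6, 2))
        model = vp.svm_train(X, np.r_[np.ones(3), -np.ones(3)])
        labels, dec = vp.svm_predict(model, np.empty((0, 2)))
        assert labels.size == 0 and dec.size == 0

    def test_single_class_rejected(self, rng):
        with pytest.raises(DataError):
            vp.svm_train(rng.normal(size=(5, 2)), np.ones(5))

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0, 1.0], [np.nan, 2.0]])
        with pytest.raises(DataError):
            vp.svm_train(X, np.array([1, -1]))

    def test_decision_matches_sklearn_reference(self, rng):
        """Our manual dual-form decision equals SVC.decision_function."""
        from sklearn.svm import SVC

        X = rng.normal(size=(20, 3))
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        if len(np.unique(y)) == 1:
            y[0] = -y[0]
        ours = vp.svm_train(X, y, sigma=0.9, C=1.0)
        ref = SVC(kernel="rbf", gamma=0.9, C=1.0, tol=1e-8).fit(X, y)
        Xnew = rng.normal(size=(7, 3))
        assert np.allclose(ours.decision(Xnew), ref.decision_function(Xnew),
                           atol=1e-10)


# ---------------------------------------------------------------------------
# confusion metrics and ROC space


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp, fn, tn, fp, se, sp, ac",
        [
            (22, 3, 25, 0, 0.88, 1.00, 0.94),  # 3 of 50 misclassified
            (25, 0, 22, 3, 1.00, 0.88, 0.94),  # 3 of 50 misclassified
        ],
    )
    def test_reported_two_model_arithmetic(self, tp, fn, tn, fp, se, sp, ac):
        pred = np.r_[np.ones(tp), -np.ones(fn), -np.ones(tn), np.ones(fp)]
        truth = np.r_[np.ones(tp + fn), -np.ones(tn + fp)]
        m = vp.confusion_metrics(pred, truth)
        assert m.sensitivity == pytest.approx(se)
        assert m.specificity == pytest.approx(sp)
        assert m.accuracy == pytest.approx(ac)
        assert m.misclassified == 3 and m.total == 50

    def test_perfect_prediction(self):
        truth = np.r_[np.ones(4), -np.ones(4)]
        m = vp.confusion_metrics(truth, truth)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0
        assert m.error_rate == 0.0

    def test_empty_class_rate_is_missing_not_zero(self):
        m = vp.confusion_metrics(np.ones(3), np.ones(3))
        assert m.specificity is None
        assert m.sensitivity == 1.0
        assert vp.roc_point(m) == (None, 1.0)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        tp=st.integers(0, 30), fn=st.integers(0, 30),
        tn=st.integers(0, 30), fp=st.integers(0, 30),
    )
    def test_accuracy_is_prevalence_weighted_rates(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        m = ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)
        P, N = tp + fn, tn + fp
        assert m.accuracy == pytest.approx(
            (m.sensitivity * P + m.specificity * N) / (P + N)
        )

    def test_roc_points(self):
        perfect = ConfusionMetrics(tp=5, tn=5, fp=0, fn=0)
        assert vp.roc_point(perfect) == (0.0, 1.0)
        all_pos = ConfusionMetrics(tp=5, tn=0, fp=5, fn=0)
        assert vp.roc_point(all_pos) == (1.0, 1.0)
        lkr = ConfusionMetrics(tp=22, tn=25, fp=0, fn=3)
        fpr, tpr = vp.roc_point(lkr)
        assert (fpr, tpr) == (0.0, pytest.approx(0.88))

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            vp.confusion_metrics(np.ones(3), np.ones(4))
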