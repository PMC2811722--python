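"""PCA projection, soft-margin RBF classification, and ROC-space metrics.

The classifier is a standard soft-margin kernel SVM with the Gaussian
kernel ``k(x, x') = exp(-sigma * ||x - x'||^2)`` — note that ``sigma``
multiplies the squared distance directly (the kernlab ``rbfdot``
convention), so the study's ``sigma = 0.9`` maps to scikit-learn's
``gamma = 0.9``.  Training delegates to libsvm via scikit-learn;
prediction is computed here from the extracted dual coefficients, bias
and support vectors, which also makes the fitted model a transparent,
serializable object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .errors import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PcaModel:
    """Centering vector, orthonormal loadings and variance fractions."""

    mean: np.ndarray
    components: np.ndarray  # (k, p), rows are loading vectors
    explained_variance_ratio: np.ndarray  # fractions of total variance

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def pca_fit(X, n_components: int | None = None) -> PcaModel:
    """Principal components from the covariance eigendecomposition.

    Centres by the column means; components are ordered by decreasing
    variance with the sign convention that each loading's
    largest-magnitude entry is positive.  ``n_components`` beyond the
    data rank is an error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise DataError("PCA needs a 2-D matrix with >= 2 samples and >= 1 feature")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    rank = int(np.sum(evals > evals[0] * 1e-12)) if evals[0] > 0 else 0
    k = rank if n_components is None else int(n_components)
    if k < 1 or k > rank:
        raise DataError(f"n_components={n_components} exceeds data rank {rank}")
    comps = evecs[:, :k].T.copy()
    for row in comps:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    total = evals.sum()
    ratio = evals[:k] / total if total > 0 else np.zeros(k)
    return PcaModel(mean=mean, components=comps, explained_variance_ratio=ratio)


def pca_project(model: PcaModel, X) -> np.ndarray:
    """Scores of ``X`` on the model's components (centred by training means)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise DataError(
            f"feature count {X.shape[1]} differs from fitted {model.mean.size}"
        )
    return (X - model.mean) @ model.components.T


# ---------------------------------------------------------------------------
# SVM


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted soft-margin RBF classifier in dual form.

    ``dual_coef`` holds the signed coefficients ``alpha_i * y_i`` of the
    support samples; the decision function is
    ``f(x) = sum_i dual_coef_i k(sv_i, x) + bias`` and the predicted
    class is its sign (+1 on ties).
    """

    sigma: float
    C: float
    support_vectors: np.ndarray = field(repr=False)
    dual_coef: np.ndarray = field(repr=False)
    support_labels: np.ndarray = field(repr=False)
    bias: float
    n_features: int

    def kernel(self, X, Y) -> np.ndarray:
        """Gaussian kernel matrix ``exp(-sigma * ||x - y||^2)``."""
        d2 = cdist(np.atleast_2d(X), np.atleast_2d(Y), "sqeuclidean")
        return np.exp(-self.sigma * d2)

    def decision(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.zeros(0)
        X = np.atleast_2d(X)
        if X.shape[1] != self.n_features:
            raise DataError(
                f"feature count {X.shape[1]} differs from trained {self.n_features}"
            )
        return self.kernel(X, self.support_vectors) @ self.dual_coef + self.bias

    def dual_objective(self) -> float:
        """Value of the dual objective at the fitted coefficients,
        ``sum(alpha) - 1/2 sum_ij alpha_i alpha_j y_i y_j k(x_i, x_j)``."""
        K = self.kernel(self.support_vectors, self.support_vectors)
        return float(
            np.sum(np.abs(self.dual_coef))
            - 0.5 * self.dual_coef @ K @ self.dual_coef
        )


def svm_train(
    X, y, sigma: float = 0.9, C: float = 1.0, tol: float = 1e-8
) -> ClassifierModel:
    """Train the soft-margin RBF classifier.

    ``y`` must contain both classes, coded +1/-1 (tumor = +1 by
    convention).  ``sigma`` scales the squared distance in the kernel;
    ``C`` is the slack penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X must be 2-D with one label per row")
    if not np.isfinite(X).all():
        raise DataError("features must be finite")
    present = set(np.unique(y).tolist())
    if present != {-1, 1}:
        raise DataError(f"labels must be -1/+1 with both classes present, got {present}")
    if sigma <= 0 or C <= 0:
        raise DataError("sigma and C must be strictly positive")
    clf = SVC(kernel="rbf", gamma=sigma, C=C, tol=tol)
    clf.fit(X, y.astype(float))
    # scikit-learn orients the decision function toward classes_[1] == +1
    return ClassifierModel(
        sigma=float(sigma),
        C=float(C),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        support_labels=np.sign(clf.dual_coef_[0]).astype(int),
        bias=float(clf.intercept_[0]),
        n_features=X.shape[1],
    )


def svm_predict(model: ClassifierModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and decision values; exact-zero decisions go to +1."""
    dec = model.decision(X)
    if np.any(dec == 0.0):
        logger.warning("decision value exactly 0 for %d samples; assigning +1",
                       int(np.sum(dec == 0.0)))
    labels = np.where(dec >= 0.0, 1, -1)
    return labels, dec


# ---------------------------------------------------------------------------
# Confusion metrics and ROC space


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and derived rates of a binary confusion table.

    Rates are fractions in [0, 1]; a rate whose denominator is empty
    (e.g. sensitivity with no positive truth) is ``None``, not 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Tally a +1/-1 prediction vector against the true labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.ndim != 1 or predicted.size == 0:
        raise DataError("predicted and truth must be equal-length non-empty vectors")
    for arr, name in ((predicted, "predicted"), (truth, "truth")):
        if not set(np.unique(arr).tolist()) <= {-1, 1}:
            raise DataError(f"{name} labels must be coded -1/+1")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == -1) & (truth == -1)))
    fp = int(np.sum((predicted == 1) & (truth == -1)))
    fn = int(np.sum((predicted == -1) & (truth == 1)))
    return ConfusionMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def roc_point(metrics: ConfusionMetrics) -> tuple[float | None, float | None]:
    """ROC-space coordinates ``(1 - specificity, sensitivity)``."""
    sp = metrics.specificity
    return (None if sp is None else 1.0 - sp, metrics.sensitivity)
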