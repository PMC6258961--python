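"""Soft-margin RBF support-vector machine component of the ensemble.

Markers are standardized (center/scale from the training data) before the
SVM is fitted; the component score is the signed decision-function value,
not the hard label.  The quadratic program is solved by libsvm (through
scikit-learn's :class:`~sklearn.svm.SVC` with a tight tolerance), but the
decision function is always evaluated here from the extracted support
vectors and dual coefficients, so that a model reloaded from disk scores
bit-identically to the freshly fitted one.

Kernel width: ``gamma="median"`` uses the median-pairwise-distance
heuristic, gamma = 1 / (2 * median(||z_i - z_j||)^2) on the standardized
training points.

Sample-weighting convention: duplicating every training sample k times is
equivalent to multiplying C by k; fitting the duplicated data with C/k
recovers the original decision function.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array


def median_distance_gamma(Z: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance heuristic."""
    d = pdist(np.asarray(Z, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("cannot set gamma: all training points coincide")
    med = float(np.median(d))
    return 1.0 / (2.0 * med * med)


class StandardizedRbfSVM(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM on standardized features exposing a signed score.

    Parameters
    ----------
    C : float, default 1.0
        Soft-margin box constraint; must be positive.
    gamma : "median" or float
        RBF width; "median" applies the median-distance heuristic on the
        standardized training data.
    min_class_count : int, default 10
        Minimum training samples per class.
    tol : float, default 1e-8
        Solver stopping tolerance (tight, so toy problems are solved to
        near machine precision).

    Attributes
    ----------
    classes_ : sorted labels; decision_function > 0 favours classes_[1].
    center_, scale_ : per-feature standardization constants.
    gamma_ : resolved kernel width.
    support_vectors_ : support vectors in standardized space.
    dual_coef_ : signed dual coefficients (y_i * alpha_i), |.| <= C.
    intercept_ : float
    """

    def __init__(self, C: float = 1.0, gamma="median", min_class_count: int = 10,
                 tol: float = 1e-8):
        self.C = C
        self.gamma = gamma
        self.min_class_count = min_class_count
        self.tol = tol

    def fit(self, X, y) -> "StandardizedRbfSVM":
        if not (np.isscalar(self.C) and self.C > 0):
            raise ValueError(f"C must be a positive number, got {self.C!r}")
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, counts = np.unique(y, return_counts=True)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {list(self.classes_)}")
        for cls, cnt in zip(self.classes_, counts):
            if cnt < self.min_class_count:
                raise ValueError(
                    f"class {cls!r} has {cnt} samples; at least "
                    f"{self.min_class_count} required"
                )
        self.center_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        if np.any(scale == 0.0):
            j = int(np.argmax(scale == 0.0))
            raise ValueError(f"feature {j} has zero variance; cannot standardize")
        self.scale_ = scale
        Z = (X - self.center_) / self.scale_
        self.gamma_ = (
            median_distance_gamma(Z) if self.gamma == "median" else float(self.gamma)
        )
        svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma_, tol=self.tol)
        svc.fit(Z, y)
        self.support_vectors_ = svc.support_vectors_.copy()
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed margin sum_i dual_i * K(sv_i, z) + b in standardized space."""
        X = check_array(X, dtype=float)
        Z = (X - self.center_) / self.scale_
        K = np.exp(-self.gamma_ * cdist(Z, self.support_vectors_, "sqeuclidean"))
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])
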