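"""Kernel-density naive Bayes component of the ensemble.

Each of the seven markers gets, per class (control / doped), a
one-dimensional Gaussian kernel density estimate with Silverman bandwidth.
The raw component score of a profile ``x`` is the naive (independence)
log-likelihood ratio

    nb(x) = sum_m [ log f_doped(x_m) - log f_control(x_m) ] + log prior odds

with equal class priors by default — the 402:189 training prevalence is a
property of how the training database was assembled, not of any athlete
population, so it is not baked into the score.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array

from .profiles import MARKERS


class KernelDensityNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes over continuous features via per-feature Gaussian KDEs.

    Parameters
    ----------
    bw_method : str or float, default "silverman"
        Bandwidth rule passed to :class:`scipy.stats.gaussian_kde`.
    priors : "equal", "empirical" or pair of floats, default "equal"
        Class priors entering the log prior odds term.
    min_class_count : int, default 10
        Minimum training samples required per class.
    feature_names : sequence of str or None
        Names used in error messages; defaults to the seven markers when
        the input has 7 columns.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``decision_function`` is positive for
        ``classes_[1]`` (with labels "control"/"doped" the positive class
        is "doped").
    kdes_ : list of lists
        ``kdes_[k][j]`` is the KDE of feature j under class k.
    log_prior_odds_ : float
    """

    def __init__(
        self,
        bw_method="silverman",
        priors="equal",
        min_class_count: int = 10,
        feature_names=None,
    ):
        self.bw_method = bw_method
        self.priors = priors
        self.min_class_count = min_class_count
        self.feature_names = feature_names

    def _names(self, n_features: int):
        if self.feature_names is not None:
            return list(self.feature_names)
        if n_features == len(MARKERS):
            return list(MARKERS)
        return [f"x{j}" for j in range(n_features)]

    def fit(self, X, y) -> "KernelDensityNaiveBayes":
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
        names = self._names(X.shape[1])
        self.kdes_ = []
        for cls in self.classes_:
            Xc = X[y == cls]
            row = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.std(col) == 0.0:
                    raise ValueError(
                        f"marker {names[j]} has zero variance within class {cls!r}"
                    )
                row.append(gaussian_kde(col, bw_method=self.bw_method))
            self.kdes_.append(row)
        if self.priors == "equal":
            pri = np.array([0.5, 0.5])
        elif self.priors == "empirical":
            pri = counts / counts.sum()
        else:
            pri = np.asarray(self.priors, dtype=float)
            pri = pri / pri.sum()
        self.class_prior_ = pri
        self.log_prior_odds_ = float(np.log(pri[1]) - np.log(pri[0]))
        self.n_features_in_ = X.shape[1]
        return self

    def _class_log_density(self, X: np.ndarray, k: int) -> np.ndarray:
        out = np.zeros(X.shape[0])
        for j in range(self.n_features_in_):
            out += self.kdes_[k][j].logpdf(X[:, j])
        return out

    def decision_function(self, X) -> np.ndarray:
        """Naive log-likelihood ratio log P(x|classes_[1]) - log P(x|classes_[0])
        plus log prior odds."""
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return (
            self._class_log_density(X, 1)
            - self._class_log_density(X, 0)
            + self.log_prior_odds_
        )

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])
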