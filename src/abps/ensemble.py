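"""The Abnormal Blood Profile Score ensemble.

The ABPS combines the seven markers into a single unitless score that is
more sensitive to blood doping than any single marker.  Two classifiers —
a kernel-density naive Bayes and an RBF support-vector machine — are
trained on a labeled cohort of control and doped profiles; their raw
scores are combined by *ensemble averaging*: each component score is
centered and scaled by its distribution over the training controls, and
the standardized components are averaged (equal weights by default).  The
averaged score is finally mapped onto the published reference scale by a
monotone quantile calibration (see :mod:`abps.calibration`).

Scoring pipeline order: validate -> clip -> NB/SVM -> ensemble-average ->
calibrate -> band.  Range clipping is part of the score's definition, so a
profile and its clipped copy score identically.

Decision bands on the calibrated scale: scores in [0, 1] indicate a
possible suspicion of doping; a score above 1 is abnormal (expected in
about 1 in 1,000 clean male athletes); scores below 0 are typical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .calibration import (
    PRESETS,
    QuantileCalibrator,
    ReferenceDistributionSpec,
    REFERENCE_ALL,
)
from .naive_bayes import KernelDensityNaiveBayes
from .profiles import (
    BloodProfile,
    DEFAULT_RANGES,
    MARKERS,
    MarkerRanges,
    clip_matrix,
    profiles_to_matrix,
)
from .svm import StandardizedRbfSVM

LABEL_CONTROL = "control"
LABEL_DOPED = "doped"

BAND_TYPICAL = "typical"
BAND_SUSPICION = "suspicion"
BAND_ABNORMAL = "abnormal"


def classify_band(abps):
    """Decision band for a calibrated score.

    ``abnormal`` if score > 1, ``suspicion`` if 0 <= score <= 1,
    ``typical`` if score < 0.  Accepts scalars or arrays.
    """
    a = np.asarray(abps, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("score must be finite")
    out = np.where(a > 1.0, BAND_ABNORMAL, np.where(a >= 0.0, BAND_SUSPICION, BAND_TYPICAL))
    return str(out[()]) if out.ndim == 0 else out


def ensemble_average(nb_raw, svm_raw, centers, scales, weights=(0.5, 0.5)):
    """Average component scores after control-population standardization.

    Each component is transformed as ``(raw - center) / scale`` with the
    constants fitted on training controls, then combined by the (normalized)
    ``weights``.  A zero component scale is an error.
    """
    centers = np.asarray(centers, dtype=float)
    scales = np.asarray(scales, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(scales == 0.0):
        raise ValueError("zero component scale; cannot standardize component scores")
    if w.sum() == 0:
        raise ValueError("ensemble weights sum to zero")
    w = w / w.sum()
    nb_z = (np.asarray(nb_raw, dtype=float) - centers[0]) / scales[0]
    svm_z = (np.asarray(svm_raw, dtype=float) - centers[1]) / scales[1]
    return w[0] * nb_z + w[1] * svm_z


class AbpsEnsemble(BaseEstimator, ClassifierMixin):
    """Trainable NB + SVM ensemble producing the calibrated ABPS score.

    Parameters
    ----------
    ranges : MarkerRanges or None
        Clipping bounds applied to every input (default physiological
        ranges with the fixed HGB bounds 12.9-18.2 g/dL).
    priors : NB class priors ("equal" by default).
    C, gamma : SVM hyperparameters (C=1, median-distance gamma).
    weights : component weights of the ensemble average.
    min_class_count : minimum training samples per class.
    random_state : recorded in the model metadata; the training procedure
        itself is deterministic given the data.

    Attributes (after :meth:`fit`)
    ------------------------------
    classes_ : sorted labels; ``classes_[0]`` is the control class.
    nb_, svm_ : fitted component estimators.
    component_center_, component_scale_ : standardization constants of the
        two component scores over the training controls.
    n_control_, n_doped_ : training class sizes.
    calibrator_ : set by :meth:`calibrate`.
    """

    def __init__(
        self,
        ranges: MarkerRanges | None = None,
        priors="equal",
        C: float = 1.0,
        gamma="median",
        weights: tuple[float, float] = (0.5, 0.5),
        min_class_count: int = 10,
        random_state: int | None = None,
    ):
        self.ranges = ranges
        self.priors = priors
        self.C = C
        self.gamma = gamma
        self.weights = weights
        self.min_class_count = min_class_count
        self.random_state = random_state

    @property
    def _ranges(self) -> MarkerRanges:
        return self.ranges if self.ranges is not None else DEFAULT_RANGES

    def fit(self, X, y) -> "AbpsEnsemble":
        X = clip_matrix(np.asarray(X, dtype=float), self._ranges)
        y = np.asarray(y)
        self.nb_ = KernelDensityNaiveBayes(
            priors=self.priors, min_class_count=self.min_class_count
        ).fit(X, y)
        self.svm_ = StandardizedRbfSVM(
            C=self.C, gamma=self.gamma, min_class_count=self.min_class_count
        ).fit(X, y)
        self.classes_ = self.nb_.classes_
        controls = X[y == self.classes_[0]]
        nb_c = self.nb_.decision_function(controls)
        svm_c = self.svm_.decision_function(controls)
        center = np.array([nb_c.mean(), svm_c.mean()])
        scale = np.array([nb_c.std(ddof=1), svm_c.std(ddof=1)])
        if np.any(scale == 0.0):
            raise ValueError("a component score is constant on training controls")
        self.component_center_ = center
        self.component_scale_ = scale
        self.n_control_ = int((y == self.classes_[0]).sum())
        self.n_doped_ = int((y == self.classes_[1]).sum())
        self.n_features_in_ = X.shape[1]
        return self

    # -- scoring -------------------------------------------------------

    def raw_score(self, X) -> np.ndarray:
        """Uncalibrated ensemble-averaged score (clips inputs first)."""
        X = clip_matrix(np.asarray(X, dtype=float), self._ranges)
        return ensemble_average(
            self.nb_.decision_function(X),
            self.svm_.decision_function(X),
            self.component_center_,
            self.component_scale_,
            self.weights,
        )

    decision_function = raw_score

    def predict(self, X):
        d = self.raw_score(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])

    def calibrate(
        self,
        raw_scores=None,
        X=None,
        spec: ReferenceDistributionSpec | str = REFERENCE_ALL,
        **kwargs,
    ) -> "AbpsEnsemble":
        """Fit the calibration map on a reference population.

        Provide either precomputed ``raw_scores`` or reference profiles
        ``X`` (which are scored first).  The map is stored on the model
        and applied to all future scores.
        """
        if isinstance(spec, str):
            spec = PRESETS[spec]
        if raw_scores is None:
            if X is None:
                raise ValueError("provide raw_scores or X")
            raw_scores = self.raw_score(X)
        self.calibrator_ = QuantileCalibrator(spec=spec, **kwargs).fit(raw_scores)
        return self

    def abps(self, X) -> np.ndarray:
        """Calibrated ABPS scores for a marker matrix."""
        if not hasattr(self, "calibrator_"):
            raise AttributeError("model is not calibrated; call calibrate() first")
        return np.asarray(self.calibrator_.transform(self.raw_score(X)))


# -- module-level operation surface -----------------------------------


def _as_matrix_labels(profiles, labels=None):
    if isinstance(profiles, pd.DataFrame):
        X = profiles[list(MARKERS)].to_numpy(dtype=float)
        if labels is None and "label" in profiles.columns:
            labels = profiles["label"].to_numpy()
    elif isinstance(profiles, (list, tuple)) and profiles and isinstance(profiles[0], BloodProfile):
        X = profiles_to_matrix(profiles)
        if labels is None:
            labels = np.array([p.metadata.get("label") for p in profiles])
    else:
        X = np.asarray(profiles, dtype=float)
    return X, (None if labels is None else np.asarray(labels))


def train_naive_bayes(cohort, labels=None, **kwargs) -> KernelDensityNaiveBayes:
    """Fit the KDE naive-Bayes component on a labeled cohort."""
    X, y = _as_matrix_labels(cohort, labels)
    return KernelDensityNaiveBayes(**kwargs).fit(X, y)


def train_svm(cohort, labels=None, C: float = 1.0, gamma="median", **kwargs) -> StandardizedRbfSVM:
    """Fit the standardized RBF-SVM component on a labeled cohort."""
    X, y = _as_matrix_labels(cohort, labels)
    return StandardizedRbfSVM(C=C, gamma=gamma, **kwargs).fit(X, y)


def train_ensemble(cohort, labels=None, **params) -> AbpsEnsemble:
    """Fit the full ensemble on a labeled cohort (profiles, frame or array)."""
    X, y = _as_matrix_labels(cohort, labels)
    return AbpsEnsemble(**params).fit(X, y)


@dataclass(frozen=True)
class ScoredProfile:
    sample_id: str
    abps: float
    band: str


def score_profiles(
    profiles: Sequence[BloodProfile] | pd.DataFrame, model: AbpsEnsemble
) -> list[ScoredProfile]:
    """Score validated profiles with a trained, calibrated ensemble.

    Each profile is clipped (with warnings), scored by both components,
    ensemble-averaged, calibration-mapped and assigned a decision band.
    Output order equals input order.
    """
    if isinstance(profiles, pd.DataFrame):
        ids = (
            profiles["sample_id"].astype(str).tolist()
            if "sample_id" in profiles.columns
            else [str(i) for i in range(len(profiles))]
        )
        X = profiles[list(MARKERS)].to_numpy(dtype=float)
    else:
        ids = [p.sample_id for p in profiles]
        X = profiles_to_matrix(profiles)
    if X.shape[0] == 0:
        return []
    Xc = clip_matrix(X, model._ranges)
    changed = np.any(Xc != X, axis=1)
    if np.any(changed):
        import warnings as _warnings

        from .profiles import ClipWarning

        bad = [ids[i] for i in np.flatnonzero(changed)]
        _warnings.warn(
            f"{len(bad)} profile(s) had value(s) outside the accepted range "
            f"and were clipped before scoring: {bad[:10]}",
            ClipWarning,
            stacklevel=2,
        )
    scores = model.abps(X)
    return [
        ScoredProfile(sid, float(s), classify_band(float(s)))
        for sid, s in zip(ids, scores)
    ]
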