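"""Schema-versioned JSON persistence for trained ensembles.

The model file stores everything needed to reproduce scores bit-exactly:
the per-marker KDE training samples and bandwidth factors, the SVM support
vectors / dual coefficients / intercept and standardization constants, the
component-score standardization constants, the calibration-map knots, the
clipping ranges and training metadata.  Floats are serialized with
shortest-repr precision, which round-trips IEEE doubles exactly.

Marker order is canonicalized on load: a file whose ``markers`` field lists
the seven markers in a different order is permuted back to canonical order,
so it scores identically.
"""

from __future__ import annotations

import json
import os
from typing import IO

import numpy as np
from scipy.stats import gaussian_kde

from .calibration import PRESETS, QuantileCalibrator, ReferenceDistributionSpec
from .ensemble import AbpsEnsemble
from .naive_bayes import KernelDensityNaiveBayes
from .profiles import MARKERS, MarkerRanges
from .svm import StandardizedRbfSVM

SCHEMA_VERSION = 1


class ModelFormatError(ValueError):
    """The model file is missing, truncated, or has an unknown schema."""


def _arr(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def model_to_dict(model: AbpsEnsemble) -> dict:
    """Serialize a trained (and optionally calibrated) ensemble to a dict."""
    if not hasattr(model, "nb_"):
        raise ValueError("model is not trained")
    nb, svm = model.nb_, model.svm_
    d = {
        "schema_version": SCHEMA_VERSION,
        "markers": list(MARKERS),
        "classes": [str(c) for c in model.classes_],
        "ranges": model._ranges.as_dict(),
        "weights": _arr(model.weights),
        "naive_bayes": {
            "class_prior": _arr(nb.class_prior_),
            "kdes": [
                [
                    {"sample": _arr(k.dataset[0]), "factor": float(k.factor)}
                    for k in row
                ]
                for row in nb.kdes_
            ],
        },
        "svm": {
            "C": float(svm.C),
            "gamma": float(svm.gamma_),
            "center": _arr(svm.center_),
            "scale": _arr(svm.scale_),
            "support_vectors": [_arr(v) for v in svm.support_vectors_],
            "dual_coef": _arr(svm.dual_coef_),
            "intercept": float(svm.intercept_),
        },
        "component_center": _arr(model.component_center_),
        "component_scale": _arr(model.component_scale_),
        "metadata": {
            "n_control": model.n_control_,
            "n_doped": model.n_doped_,
            "seed": model.random_state,
        },
    }
    if hasattr(model, "calibrator_"):
        cal = model.calibrator_
        spec = cal.spec
        d["calibration"] = {
            "spec": {
                "name": spec.name,
                "mean": spec.mean,
                "sd": spec.sd,
                "quantiles": [[p, v] for p, v in spec.quantiles],
            },
            "knots_raw": _arr(cal.knots_raw_),
            "knots_target": _arr(cal.knots_target_),
            "n_fit": cal.n_fit_,
        }
    return d


def save_model(model: AbpsEnsemble, sink: str | os.PathLike | IO[str]) -> None:
    """Write a trained ensemble to a JSON model file."""
    d = model_to_dict(model)
    if hasattr(sink, "write"):
        json.dump(d, sink, indent=1)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)


def model_from_dict(d: dict) -> AbpsEnsemble:
    """Rebuild a scoring-ready ensemble from its serialized dict."""
    if not isinstance(d, dict) or "schema_version" not in d:
        raise ModelFormatError("not an ensemble model file (no schema_version)")
    if d["schema_version"] != SCHEMA_VERSION:
        raise ModelFormatError(
            f"unsupported model schema version {d['schema_version']!r}; "
            f"this build reads version {SCHEMA_VERSION}"
        )
    try:
        stored = list(d["markers"])
        if sorted(stored) != sorted(MARKERS):
            raise ModelFormatError(f"model markers {stored} do not match {list(MARKERS)}")
        # permutation: canonical position i <- stored position perm[i]
        perm = [stored.index(m) for m in MARKERS]

        ranges = MarkerRanges({m: tuple(v) for m, v in d["ranges"].items()})
        model = AbpsEnsemble(ranges=ranges, weights=tuple(d["weights"]))
        model.classes_ = np.array(d["classes"])

        nb = KernelDensityNaiveBayes()
        nb.classes_ = model.classes_
        nb.class_prior_ = np.asarray(d["naive_bayes"]["class_prior"], dtype=float)
        nb.log_prior_odds_ = float(
            np.log(nb.class_prior_[1]) - np.log(nb.class_prior_[0])
        )
        nb.kdes_ = [
            [
                gaussian_kde(
                    np.asarray(row[j]["sample"], dtype=float),
                    bw_method=row[j]["factor"],
                )
                for j in perm
            ]
            for row in d["naive_bayes"]["kdes"]
        ]
        nb.n_features_in_ = len(MARKERS)

        sv = d["svm"]
        svm = StandardizedRbfSVM(C=sv["C"])
        svm.classes_ = model.classes_
        svm.center_ = np.asarray(sv["center"], dtype=float)[perm]
        svm.scale_ = np.asarray(sv["scale"], dtype=float)[perm]
        svm.gamma_ = float(sv["gamma"])
        svm.support_vectors_ = np.asarray(sv["support_vectors"], dtype=float)[:, perm]
        svm.dual_coef_ = np.asarray(sv["dual_coef"], dtype=float)
        svm.intercept_ = float(sv["intercept"])
        svm.n_features_in_ = len(MARKERS)

        model.nb_ = nb
        model.svm_ = svm
        model.component_center_ = np.asarray(d["component_center"], dtype=float)
        model.component_scale_ = np.asarray(d["component_scale"], dtype=float)
        model.n_control_ = int(d["metadata"]["n_control"])
        model.n_doped_ = int(d["metadata"]["n_doped"])
        model.random_state = d["metadata"]["seed"]
        model.n_features_in_ = len(MARKERS)

        if "calibration" in d:
            c = d["calibration"]
            s = c["spec"]
            spec = PRESETS.get(s["name"]) or ReferenceDistributionSpec(
                s["name"], s["mean"], s["sd"], tuple((p, v) for p, v in s["quantiles"])
            )
            cal = QuantileCalibrator(spec=spec)
            cal.knots_raw_ = np.asarray(c["knots_raw"], dtype=float)
            cal.knots_target_ = np.asarray(c["knots_target"], dtype=float)
            cal.n_fit_ = int(c["n_fit"])
            model.calibrator_ = cal
    except ModelFormatError:
        raise
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ModelFormatError(f"malformed model file: {exc}") from exc
    return model


def load_model(source: str | os.PathLike | IO[str]) -> AbpsEnsemble:
    """Read a JSON model file written by :func:`save_model`."""
    try:
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"truncated or invalid model file: {exc}") from exc
    return model_from_dict(d)
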