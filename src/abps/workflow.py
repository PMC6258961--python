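"""Convenience pipelines tying simulation, training and calibration together."""

from __future__ import annotations

import pandas as pd

from .calibration import REFERENCE_ALL, ReferenceDistributionSpec
from .ensemble import AbpsEnsemble, train_ensemble
from .profiles import MARKERS
from .simulate import CohortSpec, generate_cohort_frame


def train_default_model(
    seed: int = 0,
    calibration_size: int = 20_000,
    spec: ReferenceDistributionSpec | str = REFERENCE_ALL,
    **params,
) -> AbpsEnsemble:
    """Train and calibrate an ensemble on the default synthetic cohort.

    Fits on a 402-control / 189-doped synthetic cohort, then calibrates on
    an independent clean reference population of ``calibration_size``
    profiles drawn with a seed derived from ``seed``.
    """
    cohort = generate_cohort_frame(CohortSpec(seed=seed))
    model = train_ensemble(cohort, random_state=seed, **params)
    ref = reference_population(seed, calibration_size)
    model.calibrate(X=ref[list(MARKERS)].to_numpy(float), spec=spec)
    return model


def reference_population(seed: int, n: int) -> pd.DataFrame:
    """Clean reference cohort with a seed decorrelated from the training seed."""
    ref_seed = (int(seed) + 90_001) % (2**31)
    return generate_cohort_frame(CohortSpec(n_control=n, n_doped=0, seed=ref_seed))
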