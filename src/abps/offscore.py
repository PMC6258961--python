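"""OFF-score: an indirect marker of post-doping erythropoiesis suppression.

The OFF-score (also "OFF-hr score" or "stimulation index") combines the
hemoglobin level HGB [g/dL] and the reticulocytes percent RETP [%]:

    OFF = HGB * 10 - 60 * RETP

Hemoglobin is expected in g/dL (the factor 10 converts to g/L internally);
a heuristic unit warning fires when the value looks like it was given in
g/L.  Values typically range between 85 and 95; in the worst-case reference
population (male athlete at low altitude) a score strictly above 133 is
treated as evidence of doping.  OFF-scores are computed on raw, unclipped
marker values: range clipping applies only to the ensemble score inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import BloodProfile, UnitWarning, check_units

#: Worst-case (male, low-altitude) doping-evidence threshold.
DOPING_THRESHOLD = 133.0


@dataclass
class OffScoreResult:
    sample_id: str
    off_score: float
    flagged: bool
    warnings: list = field(default_factory=list)


def off_score(HGB, RETP, *, warn_units: bool = True):
    """Compute ``HGB*10 - 60*RETP`` (scalar or elementwise on arrays).

    Parameters
    ----------
    HGB : hemoglobin in g/dL, finite and > 0.
    RETP : reticulocytes percent, finite and >= 0.
    warn_units : emit a :class:`UnitWarning` when HGB looks like g/L
        (> 30) before computing.
    """
    h = np.asarray(HGB, dtype=float)
    r = np.asarray(RETP, dtype=float)
    if not np.all(np.isfinite(h)) or not np.all(np.isfinite(r)):
        raise ValueError("off_score: inputs must be finite")
    if np.any(h <= 0):
        raise ValueError("off_score: HGB must be > 0 (in g/dL)")
    if np.any(r < 0):
        raise ValueError("off_score: RETP must be >= 0 (in %)")
    if warn_units and np.any(h > 30.0):
        warnings.warn(
            "HGB > 30: value looks like g/L, but g/dL is expected "
            "(the formula already multiplies by 10)",
            UnitWarning,
            stacklevel=2,
        )
    out = h * 10.0 - 60.0 * r
    return float(out) if out.ndim == 0 else out


def flag_off_score(score, threshold: float = DOPING_THRESHOLD):
    """True iff ``score`` strictly exceeds ``threshold`` (default 133)."""
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("flag_off_score: score must be finite")
    out = s > threshold
    return bool(out) if out.ndim == 0 else out


def off_score_profile(
    profile: BloodProfile, threshold: float = DOPING_THRESHOLD
) -> OffScoreResult:
    """OFF-score, flag and unit warnings for one blood profile."""
    msgs = check_units(profile)
    if msgs:
        for m in msgs:
            warnings.warn(m, UnitWarning, stacklevel=2)
    score = off_score(profile.HGB, profile.RETP, warn_units=False)
    if not math.isfinite(score):
        raise ValueError(f"sample {profile.sample_id!r}: non-finite OFF-score")
    return OffScoreResult(profile.sample_id, score, flag_off_score(score, threshold), msgs)
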