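"""Blood-profile domain types, CSV I/O, validation, unit heuristics and clipping.

A blood profile is one sample's values for the seven hematological markers
used by the Abnormal Blood Profile Score:

=======  =======================================  =========
symbol   meaning                                  unit
=======  =======================================  =========
HCT      haematocrit                              %
HGB      hemoglobin concentration                 g/dL
MCH      mean corpuscular hemoglobin              pg
MCHC     mean corpuscular hemoglobin conc.        g/dL
MCV      mean corpuscular volume                  fL
RBC      red blood cell count                     10^6/uL
RETP     reticulocytes percent                    %
=======  =======================================  =========

Before scoring, each marker is clipped to a physiological range: values
outside the range are moved to the nearest bound and a warning is emitted.
Only the hemoglobin bounds (12.9-18.2 g/dL) are fixed by the scoring scheme;
the remaining defaults are wide physiological ranges and can be overridden.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical marker order used everywhere in this package.
MARKERS: tuple[str, ...] = ("HCT", "HGB", "MCH", "MCHC", "MCV", "RBC", "RETP")

MARKER_UNITS: dict[str, str] = {
    "HCT": "%",
    "HGB": "g/dL",
    "MCH": "pg",
    "MCHC": "g/dL",
    "MCV": "fL",
    "RBC": "10^6/uL",
    "RETP": "%",
}

SEXES = ("male", "female", "unknown")


class ProfileValidationError(ValueError):
    """A blood profile (or profile table) violates the input contract."""


class ClipWarning(UserWarning):
    """A marker value fell outside its accepted range and was clipped."""


class UnitWarning(UserWarning):
    """A marker value looks implausible for its declared unit."""


@dataclass
class BloodProfile:
    """One sample's seven marker values plus optional metadata.

    All marker values must be finite and strictly positive.  ``metadata``
    holds any extra columns carried along from the input table (label,
    date, ...).
    """

    sample_id: str
    HCT: float
    HGB: float
    MCH: float
    MCHC: float
    MCV: float
    RBC: float
    RETP: float
    sex: str = "unknown"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ProfileValidationError(
                f"sample {self.sample_id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        for m in MARKERS:
            v = getattr(self, m)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ProfileValidationError(
                    f"sample {self.sample_id!r}: marker {m} is not numeric ({v!r})"
                )
            v = float(v)
            if not math.isfinite(v) or v <= 0.0:
                raise ProfileValidationError(
                    f"sample {self.sample_id!r}: marker {m} must be finite and > 0, got {v!r}"
                )
            setattr(self, m, v)

    def values(self) -> np.ndarray:
        """Marker values as a length-7 array in canonical order."""
        return np.array([getattr(self, m) for m in MARKERS], dtype=float)

    def as_dict(self) -> dict:
        d = {"sample_id": self.sample_id}
        d.update({m: getattr(self, m) for m in MARKERS})
        d["sex"] = self.sex
        d.update(self.metadata)
        return d


@dataclass(frozen=True)
class MarkerRanges:
    """Per-marker [lower, upper] clipping bounds (same units as the marker)."""

    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.bounds]
        if missing:
            raise ValueError(f"MarkerRanges missing markers: {missing}")
        for m, (lo, hi) in self.bounds.items():
            if m not in MARKERS:
                raise ValueError(f"unknown marker in ranges: {m!r}")
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"marker {m}: need finite lower < upper, got [{lo}, {hi}]")

    def lower(self) -> np.ndarray:
        return np.array([self.bounds[m][0] for m in MARKERS], dtype=float)

    def upper(self) -> np.ndarray:
        return np.array([self.bounds[m][1] for m in MARKERS], dtype=float)

    def as_dict(self) -> dict[str, list[float]]:
        return {m: [float(self.bounds[m][0]), float(self.bounds[m][1])] for m in MARKERS}


# The hemoglobin bounds 12.9-18.2 g/dL are fixed by the scoring scheme; the
# other six are wide physiological ranges shipped as overridable defaults.
DEFAULT_RANGES = MarkerRanges(
    {
        "HCT": (35.0, 55.0),
        "HGB": (12.9, 18.2),
        "MCH": (24.0, 36.0),
        "MCHC": (30.0, 38.0),
        "MCV": (75.0, 105.0),
        "RBC": (3.5, 6.5),
        "RETP": (0.1, 3.0),
    }
)


@dataclass(frozen=True)
class ClipEvent:
    """Record of one marker value moved to a range bound."""

    marker: str
    original: float
    clipped: float


def clip_profile(
    profile: BloodProfile, ranges: MarkerRanges = DEFAULT_RANGES
) -> tuple[BloodProfile, list[ClipEvent]]:
    """Clip every marker of ``profile`` into its accepted range.

    Returns the clipped profile and one :class:`ClipEvent` per modified
    marker.  A :class:`ClipWarning` is emitted whenever any marker was
    out of range.  Clipping is total and idempotent.
    """
    events: list[ClipEvent] = []
    updates: dict[str, float] = {}
    for m in MARKERS:
        v = getattr(profile, m)
        lo, hi = ranges.bounds[m]
        c = min(hi, max(lo, v))
        if c != v:
            events.append(ClipEvent(m, v, c))
            updates[m] = c
    if events:
        detail = "; ".join(f"{e.marker} {e.original:g} -> {e.clipped:g}" for e in events)
        warnings.warn(
            f"sample {profile.sample_id!r}: value(s) outside the accepted range, "
            f"clipped: {detail}",
            ClipWarning,
            stacklevel=2,
        )
        profile = replace(profile, **updates)
    return profile, events


def clip_matrix(X: np.ndarray, ranges: MarkerRanges = DEFAULT_RANGES) -> np.ndarray:
    """Vectorised clipping of an (n, 7) marker matrix in canonical order."""
    X = np.asarray(X, dtype=float)
    return np.clip(X, ranges.lower(), ranges.upper())


# Unit-plausibility heuristics: (marker, predicate on value, message).
_UNIT_RULES: tuple[tuple[str, ...], ...] = (
    ("HGB", "gt", 30.0, "HGB={v:g} looks like g/L; expected g/dL (divide by 10?)"),
    ("HCT", "lt", 1.0, "HCT={v:g} looks like a fraction; expected percent (multiply by 100?)"),
    ("RETP", "gt", 25.0, "RETP={v:g} looks like an absolute count; expected percent"),
)


def check_units(profile: BloodProfile, *, warn: bool = False) -> list[str]:
    """Heuristic unit check; returns one message per implausible marker.

    The rules are deliberately coarse: HGB > 30 suggests g/L instead of
    g/dL, HCT < 1 suggests a fraction instead of percent, RETP > 25
    suggests an absolute reticulocyte count instead of percent.  An empty
    list means all values are plausible under their declared units.
    """
    msgs: list[str] = []
    for marker, op, thr, tmpl in _UNIT_RULES:
        v = getattr(profile, marker)
        hit = v > thr if op == "gt" else v < thr
        if hit:
            msgs.append(f"sample {profile.sample_id!r}: " + tmpl.format(v=v))
    if warn:
        for msg in msgs:
            warnings.warn(msg, UnitWarning, stacklevel=2)
    return msgs


def _resolve_sex(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "unknown"
    s = str(value).strip().lower()
    if s in ("m", "male"):
        return "male"
    if s in ("f", "female"):
        return "female"
    return "unknown"


def read_profiles(source, *, sep: str = ",") -> list[BloodProfile]:
    """Read blood profiles from a CSV file, path or text stream.

    The header must name (case-insensitively, any order) all seven markers.
    A ``sample_id``/``id`` column and a ``sex`` column are recognised; any
    other columns are preserved in each profile's ``metadata``.  Lines
    starting with ``#`` are ignored.  Rows with missing or non-numeric
    marker values are rejected with a logged diagnostic; the remaining rows
    are still returned, in input order.
    """
    try:
        df = pd.read_csv(
            source, sep=sep, comment="#", skip_blank_lines=True,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        warnings.warn("empty profile table", UserWarning, stacklevel=2)
        return []
    if df.shape[1] == 0 or (df.shape[0] == 0 and df.shape[1] < len(MARKERS)):
        warnings.warn("empty profile table", UserWarning, stacklevel=2)
        return []

    colmap: dict[str, str] = {}  # canonical -> actual column name
    lowered = {c.strip().lower(): c for c in df.columns}
    for m in MARKERS:
        if m.lower() not in lowered:
            raise ProfileValidationError(f"missing marker: {m}")
        colmap[m] = lowered[m.lower()]
    id_col = lowered.get("sample_id") or lowered.get("id")
    sex_col = lowered.get("sex")
    extra_cols = [
        c
        for c in df.columns
        if c not in colmap.values() and c != id_col and c != sex_col
    ]

    profiles: list[BloodProfile] = []
    n_rejected = 0
    for i, row in df.iterrows():
        sample_id = str(row[id_col]) if id_col is not None else str(i)
        try:
            vals = {}
            for m in MARKERS:
                raw = row[colmap[m]]
                v = float(raw)
                if not math.isfinite(v):
                    raise ValueError(f"marker {m} is {raw!r}")
                vals[m] = v
            profile = BloodProfile(
                sample_id=sample_id,
                sex=_resolve_sex(row[sex_col]) if sex_col is not None else "unknown",
                metadata={c: row[c] for c in extra_cols},
                **vals,
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            logger.warning("rejected row %s (sample %r): %s", i, sample_id, exc)
            continue
        profiles.append(profile)
    if df.shape[0] == 0:
        warnings.warn("empty profile table", UserWarning, stacklevel=2)
    logger.info(
        "read %d profiles (%d rows rejected)", len(profiles), n_rejected
    )
    return profiles


def write_profiles(profiles: Sequence[BloodProfile], sink, *, sep: str = ",") -> None:
    """Write profiles to CSV; inverse of :func:`read_profiles`.

    Marker values are written with full shortest-repr precision, so values
    with up to ~17 significant digits round-trip bit-exactly.
    """
    rows = [p.as_dict() for p in profiles]
    df = pd.DataFrame(rows)
    df.to_csv(sink, sep=sep, index=False)


def profiles_to_matrix(profiles: Iterable[BloodProfile]) -> np.ndarray:
    """Stack profiles into an (n, 7) marker matrix in canonical order."""
    arr = np.array([p.values() for p in profiles], dtype=float)
    return arr.reshape(-1, len(MARKERS))


def profiles_to_frame(profiles: Iterable[BloodProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame (sample_id, seven markers, sex, metadata)."""
    return pd.DataFrame([p.as_dict() for p in profiles])
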