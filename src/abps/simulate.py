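"""Synthetic athlete cohorts: clean controls and rhEPO-style doped profiles.

The original 591-profile training database (402 controls, 189 doped) is
not public, so this module generates cohorts with the statistical structure
the ensemble assumes.  Controls are drawn from a multivariate normal on the
log scale of the primary markers (HCT, HGB, RBC, RETP) around physiological
means (HGB ~14.5 g/dL for males, ~13.2 g/dL for females, RETP ~1%); the
red-cell indices are then *derived* from the primaries plus small noise, so
the hematological identities hold by construction:

    MCHC = HGB / HCT * 100   [g/dL]
    MCV  = HCT / RBC * 10    [fL]
    MCH  = MCHC * MCV / 100  [pg]

Doped profiles model rhEPO abuse in two phases, mixed 50/50 by default:
the ON phase (active stimulation: reticulocytes elevated) and the OFF
phase (after withdrawal: reticulocytes suppressed while the red-cell mass
is still high).  Both phases carry elevated HGB/HCT/RBC.  All default
effect sizes are simulation configuration, not claims about real athletes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .profiles import MARKERS, BloodProfile

# log-scale means/sds of the seven markers for a male control population;
# only the primaries (HCT, HGB, RBC, RETP) are sampled, the indices are
# derived, but the full 7-vector/7x7 parameterization is kept so any
# marker's marginal spread is inspectable and overridable.
_NATURAL_MEANS = {
    "HCT": 42.6, "HGB": 14.5, "MCH": 29.6, "MCHC": 34.0,
    "MCV": 87.0, "RBC": 4.9, "RETP": 1.0,
}
_LOG_SDS = {
    "HCT": 0.060, "HGB": 0.060, "MCH": 0.045, "MCHC": 0.015,
    "MCV": 0.045, "RBC": 0.070, "RETP": 0.400,
}
_CORR = {  # symmetric; unlisted pairs are 0
    ("HCT", "HGB"): 0.95,
    ("HCT", "RBC"): 0.80,
    ("HGB", "RBC"): 0.78,
    ("HCT", "RETP"): 0.05,
    ("HGB", "RETP"): 0.05,
    ("RBC", "RETP"): 0.05,
    ("MCV", "MCH"): 0.85,
}
# multiplicative sex adjustment for female athletes on the primary markers
_FEMALE_FACTORS = {"HCT": 13.2 / 14.5, "HGB": 13.2 / 14.5, "RBC": 0.92}

_PRIMARIES = ("HCT", "HGB", "RBC", "RETP")


def default_log_mean() -> np.ndarray:
    return np.log([_NATURAL_MEANS[m] for m in MARKERS])


def default_log_cov() -> np.ndarray:
    sd = np.array([_LOG_SDS[m] for m in MARKERS])
    corr = np.eye(len(MARKERS))
    for (a, b), r in _CORR.items():
        i, j = MARKERS.index(a), MARKERS.index(b)
        corr[i, j] = corr[j, i] = r
    return corr * np.outer(sd, sd)


@dataclass(frozen=True)
class DopingEffect:
    """rhEPO-style perturbation of a clean profile.

    Additive shifts (natural units) on the red-cell-mass markers, a
    multiplicative reticulocyte factor per pharmacodynamic phase, and an
    optional inflation of the log-scale covariance.
    """

    hgb_shift: float = 1.5     # g/dL
    hct_shift: float = 4.5     # %
    rbc_shift: float = 0.4     # 10^6/uL
    retp_on_factor: float = 2.0
    retp_off_factor: float = 0.4
    variance_inflation: float = 1.0

    def null(self) -> "DopingEffect":
        """The no-effect version (doped profiles ~ controls)."""
        return replace(
            self, hgb_shift=0.0, hct_shift=0.0, rbc_shift=0.0,
            retp_on_factor=1.0, retp_off_factor=1.0, variance_inflation=1.0,
        )


@dataclass
class CohortSpec:
    """Sizes, seed and effect parameters for synthetic cohort generation.

    Defaults mirror the composition of the original training database:
    402 control and 189 doped profiles (591 in total).
    """

    n_control: int = 402
    n_doped: int = 189
    seed: int = 0
    sex_ratio: float = 0.5          # fraction of male athletes
    log_mean: np.ndarray = field(default_factory=default_log_mean)
    log_cov: np.ndarray = field(default_factory=default_log_cov)
    effect: DopingEffect = field(default_factory=DopingEffect)
    off_phase_fraction: float = 0.5
    index_noise_sd: tuple[float, float] = (0.008, 0.012)  # log-noise on MCHC, MCV

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_doped < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")
        if not (0.0 <= self.off_phase_fraction <= 1.0):
            raise ValueError("off_phase_fraction must be in [0, 1]")
        C = np.asarray(self.log_cov, dtype=float)
        if C.shape != (7, 7) or not np.allclose(C, C.T):
            raise ValueError("log_cov must be a symmetric 7x7 matrix")
        if np.min(np.linalg.eigvalsh(C)) <= 0:
            raise ValueError("log_cov must be positive definite")


def _draw_profiles(
    rng: np.random.Generator,
    spec: CohortSpec,
    n: int,
    doped: bool,
) -> pd.DataFrame:
    idx = [MARKERS.index(m) for m in _PRIMARIES]
    mu = np.asarray(spec.log_mean, dtype=float)[idx]
    cov = np.asarray(spec.log_cov, dtype=float)[np.ix_(idx, idx)]
    if doped and spec.effect.variance_inflation != 1.0:
        cov = cov * spec.effect.variance_inflation
    L = np.linalg.cholesky(cov)

    male = rng.random(n) < spec.sex_ratio
    eta = rng.standard_normal((n, len(_PRIMARIES))) @ L.T
    logs = mu + eta
    for k, m in enumerate(_PRIMARIES):
        f = _FEMALE_FACTORS.get(m)
        if f is not None:
            logs[~male, k] += np.log(f)
    hct, hgb, rbc, retp = (np.exp(logs[:, k]) for k in range(4))

    phase = np.full(n, "", dtype=object)
    if doped:
        eff = spec.effect
        off = rng.random(n) < spec.off_phase_fraction
        phase[off] = "off"
        phase[~off] = "on"
        hgb = hgb + eff.hgb_shift
        hct = hct + eff.hct_shift
        rbc = rbc + eff.rbc_shift
        retp = retp * np.where(off, eff.retp_off_factor, eff.retp_on_factor)

    sd_mchc, sd_mcv = spec.index_noise_sd
    mchc = hgb / hct * 100.0 * np.exp(rng.normal(0.0, sd_mchc, n))
    mcv = hct / rbc * 10.0 * np.exp(rng.normal(0.0, sd_mcv, n))
    mch = mchc * mcv / 100.0
    retp = np.maximum(retp, 0.02)  # strictly positive

    df = pd.DataFrame(
        {
            "HCT": hct, "HGB": hgb, "MCH": mch, "MCHC": mchc,
            "MCV": mcv, "RBC": rbc, "RETP": retp,
            "sex": np.where(male, "male", "female"),
            "label": "doped" if doped else "control",
            "phase": phase,
        }
    )
    return df


def generate_cohort_frame(spec: CohortSpec | None = None, **overrides) -> pd.DataFrame:
    """Labeled cohort as a DataFrame (markers + sample_id, sex, label, phase)."""
    if spec is None:
        spec = CohortSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    rng = np.random.default_rng(spec.seed)
    parts = [
        _draw_profiles(rng, spec, spec.n_control, doped=False),
        _draw_profiles(rng, spec, spec.n_doped, doped=True),
    ]
    df = pd.concat(parts, ignore_index=True)
    width = max(1, len(str(max(len(df), 1))))
    df.insert(0, "sample_id", [f"S{i:0{width}d}" for i in range(1, len(df) + 1)])
    return df


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> list[BloodProfile]:
    """Labeled synthetic cohort as a list of :class:`BloodProfile`."""
    df = generate_cohort_frame(spec, **overrides)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            BloodProfile(
                sample_id=row.sample_id,
                HCT=row.HCT, HGB=row.HGB, MCH=row.MCH, MCHC=row.MCHC,
                MCV=row.MCV, RBC=row.RBC, RETP=row.RETP,
                sex=row.sex,
                metadata={"label": row.label, "phase": row.phase},
            )
        )
    return out


# -- deterministic 13-sample fixtures ---------------------------------
#
# The reference implementation ships two small datasets: blood values of 13
# presumed-clean individuals, and a 13-point longitudinal series from one
# female athlete convicted of doping.  Neither table is public here, so
# these fixtures are synthetic stand-ins built deterministically: the
# control set from the clean-cohort generator, the doping series as a
# hand-shaped rhEPO time course (rising hemoglobin, OFF-phase reticulocyte
# suppression) whose late samples should stand out under any reasonably
# trained model.

_FIXTURE_SEED = 13006


def _make_control13() -> list[BloodProfile]:
    profiles = generate_cohort(
        CohortSpec(n_control=13, n_doped=0, seed=_FIXTURE_SEED)
    )
    for i, p in enumerate(profiles, start=1):
        p.sample_id = f"C{i:02d}"
        p.metadata["label"] = "control"
    return profiles


_DOPING13 = {
    # date,        HGB,  RETP, RBC    (female athlete, synthetic time course)
    "dates": [
        "2009-03-01", "2009-09-15", "2010-02-10", "2010-08-22", "2011-01-30",
        "2011-07-12", "2012-01-05", "2012-06-18", "2012-11-29", "2013-04-14",
        "2013-09-02", "2014-02-20", "2014-07-08",
    ],
    "HGB":  [13.1, 13.4, 13.2, 13.9, 14.6, 15.2, 15.8, 16.3, 16.1, 16.8, 17.1, 17.4, 17.2],
    "RETP": [1.05, 0.98, 1.10, 0.80, 0.55, 0.45, 0.38, 0.30, 0.42, 0.28, 0.24, 0.20, 0.22],
    "RBC":  [4.35, 4.40, 4.38, 4.60, 4.85, 5.05, 5.20, 5.35, 5.30, 5.50, 5.60, 5.70, 5.65],
    "MCHC": [33.8, 34.0, 33.9, 34.1, 34.2, 34.0, 34.3, 34.1, 34.2, 34.4, 34.3, 34.5, 34.4],
}


def _make_doping13() -> list[BloodProfile]:
    out = []
    for i in range(13):
        hgb = _DOPING13["HGB"][i]
        retp = _DOPING13["RETP"][i]
        rbc = _DOPING13["RBC"][i]
        mchc = _DOPING13["MCHC"][i]
        hct = hgb / mchc * 100.0
        mcv = hct / rbc * 10.0
        mch = mchc * mcv / 100.0
        out.append(
            BloodProfile(
                sample_id=f"D{i + 1:02d}",
                HCT=hct, HGB=hgb, MCH=mch, MCHC=mchc, MCV=mcv, RBC=rbc, RETP=retp,
                sex="female",
                metadata={"label": "doped", "date": _DOPING13["dates"][i]},
            )
        )
    return out


def make_fixture(name: str) -> list[BloodProfile]:
    """Deterministic 13-profile fixtures: ``control13`` or ``doping13``.

    ``control13`` — plausible clean profiles; ``doping13`` — a synthetic
    longitudinal series for one female athlete with progressively elevated
    hemoglobin and OFF-phase reticulocyte suppression.  Both regenerate
    bit-identically across runs.
    """
    if name == "control13":
        return _make_control13()
    if name == "doping13":
        return _make_doping13()
    raise ValueError(f"unknown fixture {name!r} (expected 'control13' or 'doping13')")
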