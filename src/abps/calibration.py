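"""Calibration of raw ensemble scores to a published reference distribution.

The raw ensemble score has an arbitrary scale.  Reported scores are placed
on the reference scale by a strictly monotone piecewise-linear quantile map
fitted on a reference population: raw empirical quantiles are mapped onto a
target quantile function built from a :class:`ReferenceDistributionSpec`
(target mean/sd and/or explicit quantile anchors).

Two presets are shipped:

``reference_all``
    mean -0.67, sd 0.87, with 95% interval anchors q(0.025) = -2.35 and
    q(0.975) = 1.0 — the distribution reported for the pooled reference
    collection of test results.
``clean_male``
    the single tail anchor q(0.999) = 1.0 — a score above 1 should occur
    in about 1 in 1,000 clean male athletes.  No moment targets: the two
    statements describe different populations and are never merged.

When both moments and quantile anchors are present, the target quantile
function is the normal with the target moments, warped by a
piecewise-linear correction so the anchors are hit exactly, plus two
anchor-preserving correction shapes — a central tent (mean knob) and a
tail stretch (sd knob) — solved by damped Newton so the mapped sample
reproduces the target mean and sd while the anchors stay exact.  With
anchors only, the sample's own shape is preserved and warped through the
anchors (a pure shift when there is a single anchor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass(frozen=True)
class ReferenceDistributionSpec:
    """Target moments and/or quantiles for a calibrated score population.

    ``quantiles`` is a sequence of ``(probability, value)`` pairs; values
    must be non-decreasing in probability.  ``mean``/``sd`` may be None,
    in which case only the quantile anchors constrain the map.
    """

    name: str
    mean: float | None
    sd: float | None
    quantiles: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if (self.mean is None) != (self.sd is None):
            raise ValueError("mean and sd must be given together")
        if self.sd is not None and self.sd <= 0:
            raise ValueError("sd must be positive")
        qs = sorted(self.quantiles)
        if any(not (0.0 < p < 1.0) for p, _ in qs):
            raise ValueError("quantile probabilities must lie in (0, 1)")
        vals = [v for _, v in qs]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("quantile values must be non-decreasing in probability")
        object.__setattr__(self, "quantiles", tuple(qs))


REFERENCE_ALL = ReferenceDistributionSpec(
    "reference_all", mean=-0.67, sd=0.87, quantiles=((0.025, -2.35), (0.975, 1.0))
)
CLEAN_MALE = ReferenceDistributionSpec(
    "clean_male", mean=None, sd=None, quantiles=((0.999, 1.0),)
)
PRESETS: dict[str, ReferenceDistributionSpec] = {
    s.name: s for s in (REFERENCE_ALL, CLEAN_MALE)
}


def _interp_with_slopes(x, xp, fp):
    """Piecewise-linear interpolation with linear (not flat) extrapolation."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo_slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        hi_slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        below = x < xp[0]
        above = x > xp[-1]
        y = np.where(below, fp[0] + lo_slope * (x - xp[0]), y)
        y = np.where(above, fp[-1] + hi_slope * (x - xp[-1]), y)
    return y


class QuantileCalibrator(BaseEstimator, TransformerMixin):
    """Strictly monotone piecewise-linear map raw score -> reference scale.

    Parameters
    ----------
    spec : ReferenceDistributionSpec
        Target distribution (preset ``reference_all`` by default).
    n_knots : int
        Number of interior probability knots of the map (anchors from the
        spec are always added).  Must be at least the number of spec
        quantile anchors.
    min_n : int
        Minimum reference-sample size accepted by :meth:`fit`.

    Attributes
    ----------
    knots_raw_, knots_target_ : ndarray
        Map knots; strictly increasing in raw, non-decreasing in target.
    """

    def __init__(
        self,
        spec: ReferenceDistributionSpec = REFERENCE_ALL,
        n_knots: int = 199,
        min_n: int = 100,
    ):
        self.spec = spec
        self.n_knots = n_knots
        self.min_n = min_n

    def fit(self, X, y=None) -> "QuantileCalibrator":
        raw = np.asarray(X, dtype=float).ravel()
        if raw.size < self.min_n:
            raise ValueError(
                f"calibration needs at least {self.min_n} reference scores, got {raw.size}"
            )
        if not np.all(np.isfinite(raw)):
            raise ValueError("calibration scores must be finite")
        spec = self.spec
        if self.n_knots < len(spec.quantiles):
            raise ValueError(
                f"n_knots={self.n_knots} is fewer than the {len(spec.quantiles)} "
                "spec quantiles"
            )

        anchor_p = np.array([p for p, _ in spec.quantiles], dtype=float)
        anchor_v = np.array([v for _, v in spec.quantiles], dtype=float)
        probs = np.linspace(0.001, 0.999, self.n_knots)
        # extreme-tail knots down to the sample min/max keep the map (and
        # hence the mapped moments) under control on heavy-tailed raw scores
        p_min = 0.5 / raw.size
        tails = np.array([p_min, 1e-5, 1e-4, 1 - 1e-4, 1 - 1e-5, 1 - p_min])
        tails = tails[(tails > 0) & (tails < 1)]
        probs = np.unique(np.concatenate([probs, anchor_p, tails]))
        raw_q = np.quantile(raw, probs)

        # collapse ties on the raw side so the map is a function
        keep = np.concatenate([[True], np.diff(raw_q) > 0])
        probs, raw_q = probs[keep], raw_q[keep]

        def _anchored_target(base: np.ndarray) -> np.ndarray:
            if not anchor_p.size:
                return base
            delta = anchor_v - np.interp(anchor_p, probs, base)
            # piecewise-linear correction through the anchors, constant
            # beyond the outermost anchor
            return np.maximum.accumulate(base + np.interp(probs, anchor_p, delta))

        def _moments(target: np.ndarray) -> tuple[float, float]:
            mapped = _interp_with_slopes(raw, raw_q, target)
            return float(np.mean(mapped)), float(np.std(mapped, ddof=1))

        if spec.mean is None:
            # shape-preserving: warp the sample's own quantiles through the
            # anchors (a pure shift for a single anchor)
            target = _anchored_target(raw_q.copy())
        elif anchor_p.size < 2:
            # not enough anchors to add moment knobs that keep them fixed:
            # affine moment fit first, anchor warp last (anchors exact,
            # moments approximate)
            z = stats.norm.ppf(probs)
            m0, s0 = spec.mean, spec.sd
            for _ in range(100):
                mu, sd = _moments(m0 + s0 * z)
                if abs(mu - spec.mean) < 1e-12 and abs(sd - spec.sd) < 1e-12:
                    break
                m0 += spec.mean - mu
                s0 *= spec.sd / sd
            target = _anchored_target(m0 + s0 * z)
        else:
            # anchored normal base plus two anchor-preserving correction
            # shapes: a central tent (mean knob) and a tail stretch in
            # normal-quantile units (sd knob), solved by damped Newton
            z = stats.norm.ppf(probs)
            base = _anchored_target(spec.mean + spec.sd * z)
            p1, p2 = anchor_p[0], anchor_p[-1]
            z1, z2 = stats.norm.ppf([p1, p2])
            t_sd = np.where(probs > p2, z - z2, np.where(probs < p1, z - z1, 0.0))
            half = (p2 - p1) / 2.0
            t_mean = np.clip(1.0 - np.abs(probs - (p1 + p2) / 2.0) / half, 0.0, None)

            def _target(a: float, b: float) -> np.ndarray:
                return np.maximum.accumulate(base + a * t_mean + b * t_sd)

            a = b = 0.0
            for _ in range(50):
                mu, sd = _moments(_target(a, b))
                r = np.array([mu - spec.mean, sd - spec.sd])
                if np.max(np.abs(r)) < 1e-11:
                    break
                eps = 1e-5
                mu_a, sd_a = _moments(_target(a + eps, b))
                mu_b, sd_b = _moments(_target(a, b + eps))
                J = np.array(
                    [[(mu_a - mu) / eps, (mu_b - mu) / eps],
                     [(sd_a - sd) / eps, (sd_b - sd) / eps]]
                )
                try:
                    step = np.linalg.solve(J, r)
                except np.linalg.LinAlgError:
                    break
                step = np.clip(step, -0.5, 0.5)
                a -= float(step[0])
                b -= float(step[1])
            target = _target(a, b)

        self.knots_raw_ = raw_q
        self.knots_target_ = np.maximum.accumulate(target)
        self.n_fit_ = int(raw.size)
        return self

    def transform(self, X):
        if not hasattr(self, "knots_raw_"):
            raise AttributeError("QuantileCalibrator is not fitted")
        x = np.asarray(X, dtype=float)
        out = _interp_with_slopes(x.ravel(), self.knots_raw_, self.knots_target_)
        return out.reshape(x.shape) if x.ndim else float(out[0])

    __call__ = transform


def calibrate(
    raw_scores: Sequence[float],
    spec: ReferenceDistributionSpec | str = REFERENCE_ALL,
    **kwargs,
) -> QuantileCalibrator:
    """Fit a :class:`QuantileCalibrator` on a reference score sample."""
    if isinstance(spec, str):
        spec = PRESETS[spec]
    return QuantileCalibrator(spec=spec, **kwargs).fit(raw_scores)
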