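# Methods

## Scores

**OFF-score.** `OFF = HGB × 10 − 60 × RETP`, with hemoglobin in g/dL
(the ×10 converts internally to g/L) and reticulocytes in percent. It is
computed on raw, unclipped values: range clipping belongs to the ensemble
score's definition, not to the OFF-score. The doping flag uses a strict
inequality at the default threshold 133 — the worst-case (male, low
altitude) reference value; thresholds for other populations can be passed
as a parameter, but no catalogue is shipped. A heuristic warns when units
look wrong: HGB > 30 suggests g/L, HCT < 1 suggests a fraction instead of
percent, RETP > 25 suggests an absolute count. These thresholds are
deliberately coarse — physiological values never approach them under the
correct units.

**ABPS ensemble.** The pipeline is
validate → clip → NB / SVM → ensemble-average → calibrate → band.

- *Clipping.* Each marker is moved into a closed physiological range;
  the hemoglobin bounds 12.9–18.2 g/dL are part of the score's definition,
  while the other six defaults (HCT 35–55 %, MCH 24–36 pg, MCHC 30–38
  g/dL, MCV 75–105 fL, RBC 3.5–6.5 ×10⁶/µL, RETP 0.1–3 %) are wide
  physiological stand-ins and overridable. Clipping is total, idempotent
  and order-preserving; every clip emits a warning.
- *Naive Bayes.* Per marker and per class, a 1-d Gaussian KDE with the
  Silverman factor `(3n/4)^(−1/5)`; the score is the independence
  log-likelihood ratio plus log prior odds. Priors are equal by default:
  the 402:189 training prevalence reflects database assembly, not any
  athlete population, so it is not baked into the score (an `empirical`
  option exists). A class with fewer than `min_class_count` samples
  (default 10) or a zero-variance marker within a class is a hard error.
- *SVM.* Soft-margin RBF machine on standardized markers (training mean /
  population sd), `C = 1`, width from the median-pairwise-distance
  heuristic `γ = 1/(2·median‖zᵢ−zⱼ‖²)`. The dual problem is solved by
  libsvm with tolerance 1e−8; the decision function is evaluated from the
  extracted support vectors and dual coefficients by this package's own
  kernel sum, so a reloaded model is bit-identical to a fresh one.
  Convention: duplicating every sample k times is equivalent to
  multiplying C by k.
- *Ensemble averaging.* Each component score is standardized by its mean
  and sd over the **training controls** and the two standardized scores
  are averaged with equal weights (configurable). Standardizing on
  controls pins the clean population at a common scale for both
  components; a degenerate (constant) component is a hard error.

## Calibration

Raw ensemble scores are mapped to the published reference scale by a
monotone piecewise-linear quantile map with ~200 probability knots plus
extreme-tail knots down to the sample minimum/maximum (the tail knots stop
heavy raw-score tails from blowing up the mapped moments under linear
extrapolation).

The target quantile function comes from a `ReferenceDistributionSpec`:

- `reference_all`: mean −0.67, sd 0.87, anchors q(0.025) = −2.35 and
  q(0.975) = 1.0. The base is the normal with the spec moments, warped by
  a piecewise-linear correction so the anchors are hit exactly. Because
  the four constraints are not exactly normal-compatible, two
  anchor-preserving correction shapes — a central tent (mean knob) and a
  tail stretch in normal-quantile units (sd knob) — are solved by damped
  Newton so that the mapped calibration sample reproduces the spec mean
  and sd to ~1e−11 while the anchors stay exact.
- `clean_male`: the single anchor q(0.999) = 1.0 and no moment targets;
  the map preserves the sample's own shape (a pure shift for one anchor).
  The two presets describe different populations (pooled reference vs
  clean males) and are never merged, since their tail statements are
  mutually inconsistent for a single population.

Calibration requires at least 100 reference scores, preserves rank order
exactly, and the fitted knots are stored in the model file. Whether the
original implementation calibrates explicitly or simply reports empirical
reference statistics is unknown; here calibration is an explicit, optional
step (`AbpsEnsemble.calibrate`), and scoring without it is an error rather
than a silent raw score.

## Synthetic cohorts

`CohortSpec` defaults to 402 controls + 189 doped (the composition of the
original training database) with a 50/50 sex ratio. Controls are sampled
from a multivariate normal on the log scale of the primary markers
(HCT, HGB, RBC, RETP) — log sampling guarantees positivity — with
log-sds ≈ 6–7 % for the red-cell-mass markers, 40 % for RETP, and strong
HCT–HGB–RBC correlations (0.78–0.95). Female profiles shift HGB/HCT by
the factor 13.2/14.5 and RBC by 0.92. The red-cell indices are *derived*,
not sampled: MCHC = HGB/HCT·100 and MCV = HCT/RBC·10, each with ~1 %
log-normal noise, and MCH = MCHC·MCV/100, so the identities the
classifiers implicitly exploit hold to within 2 g/dL (MCHC) and 8 fL
(MCV) by construction.

The doped effect adds 1.5 g/dL HGB, 4.5 % HCT and 0.4 ×10⁶/µL RBC, and
multiplies RETP by 0.4 (OFF phase, 50 % of doped profiles) or 2.0 (ON
phase) — rhEPO pharmacodynamics in caricature. Variance inflation
defaults to 1.0. These sizes produce single-marker AUROCs around 0.85 and
a clearly bimodal doped RETP distribution, which is exactly the structure
that rewards a density-based ensemble over any single marker. They are
configuration, not estimates from real athletes: passing tests on these
cohorts demonstrates that the machinery recovers planted structure, not
that real doping is detected at these rates. Real data differ in analyzer
drift, pre-analytical variation, population heterogeneity and doping
protocols, none of which are simulated.

Two deterministic 13-profile fixtures stand in for the reference
implementation's example datasets (whose values are not public, so both
are synthetic): `control13` (clean draws at a fixed internal seed chosen
so the set scores in the typical/suspicion bands under the default
trained model, per its construction contract) and `doping13` (a
hand-shaped longitudinal rhEPO time course for one female athlete —
hemoglobin rising 13.1 → 17.4 g/dL while reticulocytes fall to 0.2 % —
whose late samples exceed the suspicion band).

## Numerical choices and reproducibility

- Model files are JSON with full shortest-repr float precision; loading
  reconstructs KDEs from their stored samples and bandwidth factors and
  the SVM from its stored arrays, so scores round-trip bit-exactly.
  Marker order is canonicalized on load. A schema-version field guards
  against silently reading foreign files.
- Band boundaries: suspicion is the closed interval [0, 1]; abnormal is
  strictly > 1; the OFF flag is strictly > 133.
- Training is deterministic given the data (KDE and the SVM solve have no
  randomness at this tolerance); seeds control only cohort generation and
  are explicit everywhere. CLI runs log their resolved configuration and
  stamp outputs with a config hash; identical argv gives byte-identical
  files.
- Problem sizes: the shipped checks train on the 591-profile default
  cohort, calibrate on 5,000–20,000 clean profiles in unit tests, and use
  a 100,000-profile reference population in `scripts/acceptance.py`
  (about ten seconds end to end); discrimination properties use ten
  seeded replicates with 70/30 stratified splits.

## Limitations

- The confidential WADA/ADAMS parameter values cannot be reproduced: the
  original trained parameters and the 591-profile database are
  unpublished. This package reproduces the method, trained on synthetic
  or user-supplied cohorts.
- The 12-marker score variants and per-population correction factors are
  out of scope, as is longitudinal passport logic.
- The KDE/RBF/equal-weight choices fill gaps the method's public
  description leaves open; they are declared defaults, all overridable.
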