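# Methods

## Scope and data model

The pipeline consumes vessel-segment annotations (not raw video): each
analyzable clip is a list of segments with length (mm, or a polyline in mm
coordinates), lumen diameter (µm) and a flow grade in {0, 1, 2, 3}, plus the
field-of-view geometry. Cohorts are long-format tables of per-video metric
values for two arms — preoperative controls measured once, and shock
patients measured at baseline, 3 minutes and 30 minutes after a topical
nitroglycerin microdose — with optional per-video quality factors and
per-timepoint hemodynamics.

## Metric conventions

- **Vessel classes.** Small ≤ 20 µm (inclusive), venule (20, 30] µm
  (inclusive upper bound), wider excluded. Venules contribute only to RBC
  velocimetry, never to the densities.
- **Perfusion dichotomy.** Grades 2 (sluggish) and 3 (continuous) are
  perfused; 0–1 are not.
- **PPV and PVD are length-weighted.** This keeps the identity
  PVD = TVD · PPV/100 exact in mm/mm² units; a count-based PPV variant used
  by some software is deliberately not implemented (the densities would no
  longer be mutually consistent). PPV is undefined (error), not zero, when a
  field has no small-vessel length.
- **MFI** uses the quadrant-modal convention: the field is split into a
  2 × 2 grid, each quadrant contributes the modal small-vessel grade, and
  the MFI is the mean over populated quadrants. Modal ties break toward the
  **lower** grade — the conservative choice for a perfusion score. Empty
  quadrants are skipped with a warning; a vessel-averaged variant
  (`method="vessel"`) is available since reports rarely state which
  convention was used.
- **MHI** is (max − min)/mean of the MFIs across one timepoint's video
  replicates. It is undefined for a single video or zero mean.

## RBC velocimetry

Velocity is the streak slope of a space-time diagram scaled by the
calibrations, v = s · (µm/px)/(s/row). The slope estimator shears the image
by a candidate slope (with wraparound, matching streaks that re-enter the
field) and scores the variance of the time-collapsed column profile, which
peaks when the shear cancels the true motion.

Numerical design: the peak half-width is roughly streak-width / rows
projected (~0.02 px/row for a 1 px streak over 120 rows), far narrower than
any affordable flat grid. The search therefore starts on a short time
window (10 rows), where the peak spans ~0.1 px/row and a 0.1 px/row grid
cannot miss it, then grows the window by 4× per stage while shrinking the
bracket, and finishes with parabolic interpolation. The slope grid is
capped at 3,000 µm/s (venular velocities above this are not physiological)
and at one field-width per row (beyond which wraparound aliases). Only the
speed is estimated; direction is not modelled. Per-video aggregation uses
the median across diagrams with MAD·1.4826 as dispersion, robust to an
occasional runaway streak. A flat diagram raises "no streak signal".

Default calibrations: 1.0 µm/px spatial, 0.05 s/row temporal (a six-second,
120-frame clip sampled once per frame); both configurable everywhere.

## Quality gating and agreement

The six Massey factors each score 0 (good), 1 (acceptable) or 10
(unacceptable); the gate keeps videos with total **strictly below 10**, so a
single unacceptable factor excludes a clip. Bland–Altman agreement uses
bias = mean difference and limits bias ± 1.96 · SD(differences) (sample SD);
the 10% double-coding subsample is a seeded uniform draw without
replacement.

## Responder statistic

Per shock patient, the sample variance (n − 1 denominator, the unbiased
pooled-variance convention) of the baseline PVD video replicates; variances
averaged across patients; pooled SD σ̂ is the square root. The response
threshold is k·σ̂ with k = 1.8 (one-sided 90% confidence — only an increase
is expected). The per-patient effect is Δ = mean PVD(3 min) − mean
PVD(baseline), both timepoint means across that patient's videos, and a
responder satisfies Δ > k·σ̂ strictly. Patients without ≥ 2 baseline
replicates or without post-dose videos are excluded with a warning (they
could optionally be classified against the cohort threshold, but exclusion
is the default).

The threshold is always derived from the full-precision pooled SD.
`audit_printed_threshold` exists because published reports often print a
rounded SD next to a threshold computed from the unrounded one
(1.8 × 3.03 = 5.454 prints as 5.45, while an unrounded SD of ~3.033 prints
as 3.03 yet yields 5.46); the audit flags exactly this mismatch.

Under the null, Δ is Gaussian with SD σ·√(1/n₃ + 1/n_b), so with three
videos per timepoint the per-patient false-positive rate is
Φ̄(1.8/√(2/3)) ≈ 1.4%, not 10%: the 1.8 SD rule is calibrated against a
single measurement's noise, and averaging replicates makes it conservative.
The test suite verifies this against a brute-force simulation.

## Cohort statistics

- Normality gate: D'Agostino–Pearson omnibus test at α = 0.05; below its
  validity floor (n < 8) or for constant data the gate returns non-normal
  with a warning. Routing: both groups normal → Student *t* (equal
  variances, two-sided); otherwise Mann–Whitney U. Identical groups return
  p = 1 rather than NaN.
- Repeated measures: standard one-way within-subject decomposition
  (listwise deletion, reported), sphericity-uncorrected F by default with an
  optional Greenhouse–Geisser switch (epsilon via pingouin). Pairwise
  contrasts against baseline use Tukey's HSD on the within-subject error
  mean square via the studentized-range distribution — implemented
  in-package because no installed library exposes Tukey on the RM error
  term; the omnibus F is cross-checked against `pingouin.rm_anova` in the
  tests.
- Vasoactive scores: VIS = dopamine + dobutamine + 100·epinephrine +
  100·norepinephrine + 10·milrinone (µg/kg/min) + 10,000·vasopressin
  (units/kg/min) + 10·phenylephrine (µg/kg/min); norepinephrine equivalents
  default to epinephrine 1:1, dopamine 1:100, phenylephrine 1:10,
  vasopressin 2.5 per unit/min. Both are configurable tables, since the
  equivalence literature varies. Doses reported per minute rather than per
  kg·minute are converted with the patient's weight, defaulting to 80 kg
  with a warning when no weight is available.
- Rendered tables report mean ± SD formatted to two decimals alongside the
  full-precision columns.

## Synthetic data generator

**Vessel maps.** Segments are three-point, mildly curved polylines whose
arc length is the controlled quantity; when a target TVD is given, segment
lengths are drawn proportionally and normalized so the summed small-vessel
length equals target · area exactly. Default field of view 1.55 × 1.16 mm
(typical of the device class). The default of 150 small vessels makes
table-scale densities (~40 mm of vessel per field) realistic 0.1–0.4 mm
segments.

**Space-time diagrams.** Gaussian-profile streaks (width 1.2 px, amplitude
1) advancing at the planted slope with wraparound, plus additive Gaussian
noise; "20% noise" in the tests means noise SD = 0.2 of streak amplitude.

**Cohorts.** The generator emulates the study conditions:

- 20 + 20 patients; three baseline videos per shock patient (the number the
  pooled variance is defined on) and, as a symmetric default, three videos
  at each follow-up timepoint (reports rarely state the follow-up count;
  it is a parameter).
- Per-video PVD = patient mean + N(0, σ_w) with σ_w = 3.03 mm/mm², the
  pooled-SD calibration. Patient-level means are drawn with a **shrunken
  between-patient SD** √(SD_table² − σ_w²/n videos) so the observed SD of
  patient means reproduces the published table SDs rather than inflating
  them.
- Per-video PPV is drawn likewise (clipped to (1, 100]); **TVD is derived**
  as PVD/(PPV/100) so the density identity holds on every generated video.
  The induced TVD mean (PVD mean / PPV mean) lands within ~1% of the table
  value; TVD is deliberately not generated independently, which would break
  the identity.
- Per-video MFI noise is derived from the target heterogeneity index:
  E[MHI] ≈ E[range of n replicates]/mean, so σ_MFI = MHI·MFI/d₂(n) with
  Hartley's d₂ (1.69 at n = 3). Heterogeneity is thus an emergent property
  of the replicate noise, as it is in real data.
- **Responder effect.** The published 3-minute PVD increase (+5.97 mm/mm²)
  is a mean over all 20 shock patients, responders and non-responders
  together. The generator therefore plants the cohort-mean increase: with
  responder fraction f = 13/20 and non-responder effect 0 (a non-responder
  has no drug effect — the parsimonious model), the per-responder effect is
  5.97/f = 9.18 mm/mm² (3.03 pooled SDs). Planting 5.97 per responder
  instead would contradict what the published mean measures, and no
  threshold rule can reach 90% sensitivity at that effect size: SD(Δ) =
  σ√(2/3) = 2.47, so power at a 5.454 threshold would be Φ((5.97−5.454)/2.47)
  ≈ 0.58 even in the infinite-replicate limit (≤ 0.62). At the planted
  9.18, recovery runs at ~0.93 sensitivity / ~0.98 specificity, and the
  expected recovered count is ~12.3 of 13.
- Responders' 3-minute PPV is drawn at the published post-dose level and
  TVD re-derived, so recruitment raises TVD and PPV jointly; MFI and RBCv
  get per-responder effects scaled by 1/f so the cohort means match the
  post-dose table. At 30 minutes every patient reverts to their own
  baseline means (fresh replicate noise).
- Massey factors are drawn per video (minor penalty 4%, major 0.1% per
  factor, giving a mean total ≈ 0.3 and rare exclusions); simple Gaussian
  hemodynamic scalars (MAP, CVP, CI) are attached per timepoint with no
  drug effect.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: spatial correlation of perfusion within a field,
pressure-artifact structure, non-Gaussian replicate noise, correlation
between metrics beyond the density identity, drop-out/missing videos, and
any secular drift between timepoints. Parameter-recovery results are
statements about the pooled-variance machinery under its own noise model,
not about IDF measurement physics.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale sizes chosen as
sensible defaults for a laptop run: 200 seeded cohorts for responder
recovery, 1,000 random annotations for the metric oracle, 8 noiseless + 100
noisy diagrams (120 × 256 px) for velocimetry, 10,000 replicates for the
type-I-error calibration and 1,000 permutations for the repeated-measures
oracle. Degenerate inputs fail loudly (zero-area fields, missing quality
scores, sub-minimum replicate counts, flat diagrams, out-of-range grades)
rather than returning sentinel values; the only silent conventions are the
documented clips of generated PPV/MFI to their physical ranges.

## Known limitations

- Only length-based densities are implemented; grid-crossing (De Backer)
  density is out of scope.
- The velocimetry assumes a dominant single velocity per diagram; bimodal
  flow yields the stronger population's slope.
- The repeated-measures pairwise contrasts assume the balanced three-
  timepoint design; arbitrary contrast sets are not supported.
- The deposited-dataset adapter maps schemas; it does not validate units.
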