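# microcirc

Analysis pipeline for sublingual microcirculation studies of topical
vasodilator (nitroglycerin) challenges in circulatory shock, built for
handheld incident dark-field (IDF) videomicroscopy workflows: consensus
microcirculation metrics from vessel-segment annotations, red-blood-cell
velocimetry from space-time diagrams, Massey video-quality gating, a
pooled-variance pharmacodynamic responder statistic, and the repeated-
measures cohort statistics that produce study-style summary tables. A
seeded synthetic-data generator with planted ground truth makes every stage
testable at desk scale.

## Who it is for

Researchers quantifying the sublingual microcirculation from annotated IDF
video clips (e.g. AVA-style segment tables) who need reproducible,
scriptable versions of the consensus metrics and of a patient-specific
drug-response criterion, instead of spreadsheet pipelines.

## The science in brief

**Consensus metrics.** Each video clip is annotated as vessel segments with
a length (mm), a lumen diameter (µm) and a semiquantitative flow grade
(0 no flow, 1 intermittent, 2 sluggish, 3 continuous). Only small vessels
(diameter ≤ 20 µm) enter the density metrics; venules (20–30 µm) are used
for velocimetry only. With field area *A* (mm²),

- TVD = Σ length(small) / *A*  (mm/mm²)
- PPV = 100 · Σ length(small, grade ∈ {2,3}) / Σ length(small)  (%)
- PVD = TVD · PPV / 100  (mm/mm²)
- MFI = mean over the four field quadrants of the modal small-vessel grade
- MHI = (max MFI − min MFI) / mean MFI across one timepoint's videos

**RBC velocimetry.** A space-time diagram samples a venule centerline over
time; moving cells trace streaks with slope *s* px/row and velocity
*v = s · (µm/px) / (s/row)*. The dominant slope is recovered by a
coarse-to-fine shear-and-project search that maximizes the variance of the
time-collapsed intensity profile.

**Quality gating.** Videos are scored on six factors (illumination,
duration, focus, content, stability, pressure; penalties 0/1/10) and kept
only when the total Massey score is strictly below 10. Inter-rater
agreement is summarized by Bland–Altman bias and 95% limits of agreement.

**Responder statistic.** Each shock patient's three baseline PVD videos
give a sample variance; variances are averaged across the cohort and the
pooled SD σ̂ is the square root. A patient is a pharmacodynamic responder
when their PVD increase from baseline to 3 minutes post-dose strictly
exceeds 1.8 σ̂ (a one-sided 90% confidence criterion). Exposed as a
scikit-learn-style estimator (`ResponderClassifier`).

**Cohort statistics.** Two-group comparisons are routed by a
D'Agostino–Pearson normality gate to Student *t* or Mann–Whitney *U*;
timepoint effects use one-way repeated-measures ANOVA with Tukey-adjusted
contrasts against baseline; vasoactive support is summarized by the
vasopressor-inotrope score and norepinephrine equivalents (configurable
coefficient tables).

## Worked example

```python
import microcirc as mc

# a synthetic 20 + 20 patient cohort calibrated to published shock-study
# distributions, with a planted 13/20 responder subgroup
cohort, truth = mc.generate_cohort(mc.CohortParams(seed=7))
gated = cohort.apply_quality_gate()          # Massey < 10
res = mc.classify_responders(gated)          # pooled-variance statistic
print(f"pooled baseline SD : {res.pooled_sd:.2f} mm/mm^2")
print(f"response threshold : {res.threshold:.2f} mm/mm^2 (k = {res.k})")
print(f"responders         : {res.n_responders} / 20")

# RBC velocity from a noisy synthetic space-time diagram
d, t = mc.generate_space_time_diagram(true_velocity_um_s=700.0,
                                      noise_sd=0.2, seed=3)
slope = mc.estimate_slope(d)
print(f"slope {slope:.2f} px/row -> {mc.slope_to_velocity(slope, 1.0, 0.05):.1f} um/s")
```

prints

```
pooled baseline SD : 3.40 mm/mm^2
response threshold : 6.12 mm/mm^2 (k = 1.8)
responders         : 11 / 20
slope 35.00 px/row -> 700.0 um/s
```

The pooled SD estimates the planted replicate noise (3.03 mm/mm²; with 40
degrees of freedom a single cohort scatters around it), the threshold is
1.8 pooled SDs, and the responder count recovers the planted 13/20 split up
to the noise of a 20-patient cohort. The velocimetry estimate inverts the
planted 700 µm/s exactly at this noise level.

A `microcirc` console script wraps the same stages
(`microcirc simulate-cohort`, `simulate-diagram`, `velocity`, `respond`,
`report`); external cohorts in foreign schemas are adapted with
`microcirc.io.load_deposited_cohort`, which requires an explicit column
mapping and never guesses columns.

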