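# Methods

`tivbias` implements a confound-aware sex-classification workflow for
grey-matter-volume (GMV) features and audits the resulting models for
brain-size bias.  This note documents the model, the synthetic data the
package is exercised on, the numerical choices, and the limits of what the
tests demonstrate.

## The problem

Men have, on average, a larger total intracranial volume (TIV) than women.
Any classifier trained to predict sex from structural brain features can
therefore reach high accuracy by learning brain *size* rather than brain
*organisation*: it will classify large-brained subjects as male and
small-brained subjects as female, and its errors will concentrate on
subjects with intermediate TIV.  Such a model is misleading wherever TIV and
the question of interest are entangled — most acutely when a cisgender-trained
classifier is applied to transgender cohorts whose TIV may sit between the
cisgender means.

The package compares two remedies on a common footing:

* **featurewise confound removal** (`+cr` models): after dimensionality
  reduction, each component score is residualised against TIV with ordinary
  least squares whose coefficients are learnt on training data only and
  re-used unchanged on test data;
* **stratification by matching** (ATM models): the training sample is built
  from woman–man pairs drawn within scanning site whose ages differ by at
  most 1 year and whose TIVs differ by at most 3%, which equalises the TIV
  distribution across the sexes before any model sees the data.

The four-model grid is {AM, AM+cr, ATM, ATM+cr}, where AM is the age-matched
(TIV-naive) baseline and the `+cr` variants add confound removal.

## Classification pipeline

Features are mean-centred (no variance scaling: GMV features share units)
and decomposed by PCA retaining `min(n_subjects, n_features)` components; at
most `n_subjects - 1` of these carry nonzero variance after centering.  An
RBF-kernel SVM is tuned over log-uniform C ∈ [1, 1e8] and γ ∈ [1e-7, 1] by a
seeded random search scored with inner stratified 5-fold cross-validated
balanced accuracy; the search budget defaults to 250 candidates, with 25
used by the desk-scale experiment driver.  Inside every fold the PCA and, if
enabled, the confound remover are refit on that fold's training half — the
same cross-validation-consistent discipline applied at every level, so that
no statistic of any evaluation subject can leak into fitting.

Class probabilities come from a Platt-style sigmoid: a logistic regression
fit to out-of-fold SVM decision scores (5-fold, full pipeline refit per
fold).  The map is monotone by construction; if the fitted slope is negative
(uninformative scores), the identity map is used instead.  The decision
threshold is fixed at P(male) = 0.5, ties labelled male.

**Confound-remover extrapolation guard.**  A per-component linear fit of
score on TIV is only trusted on the TIV support it was learnt on.  When a
remover trained on a TIV-matched sample (narrow TIV range) is applied to a
natural-population sample (wide range), evaluating the fitted line far
outside the training support multiplies coefficient noise by the TIV
excursion and can swamp the signal.  `apply_confound_remover` therefore
clips test TIV into the fitted range before computing fitted values; beyond
the support, the correction is held constant.  This is a numerical
safeguard, not a modelling claim, and can be disabled per remover.

## Bias audit

Subjects are partitioned per group (W/M on cisgender hold-outs; CW/CM/TM/TW
on application samples) into those classified **congruently** vs
**incongruently** with their sex assigned at birth.  TIV and total-GMV
distributions of the two subsets are compared with two-sided Wilcoxon
rank-sum tests at a conservative α = 0.005: mid-ranks for ties, tie-corrected
variance, 0.5 continuity correction, `T` reported as the rank-sum of the
congruent group, and the rank effect size η² = z²/N.  Cohen's d for
prediction-probability comparisons (CW vs TM, CM vs TW, α = 0.05) uses the
pooled-t identity d = t·√(1/n₁ + 1/n₂).  These conventions were chosen
because they are the standard textbook forms and are mutually consistent;
exact tie handling in the source protocol is not published, so small
discrepancies in the second decimal of z are expected on tied data.

The verdict is "bias detected" iff some group's TIV test is significant in
the biased direction (congruent men larger than incongruent men, or
congruent women smaller than incongruent women); a model that misclassifies
nobody is "not assessable from misclassifications".

## Synthetic cohorts

No MRI data ships with the package.  The generator emulates the statistical
structure the analysis assumes, with every knob explicit:

| parameter | default | meaning |
| --- | --- | --- |
| `tiv_mean_female/male` | 1350 / 1550 ml | per-sex TIV Normal means |
| `tiv_sd` | 120 ml | per-sex TIV SD (overlapping distributions) |
| `scaling_leak` | 0.8 | fraction of TIV-driven global scaling surviving imperfect correction |
| `signal_amplitude` | 0.5 | strength of the sex-typed pattern (unit-norm direction) |
| `signal_sparsity` | 0.1 | fraction of features carrying the pattern before orthogonalisation |
| `age_slope` | −0.002 /yr | linear GMV decline per feature-loading unit (≈10% over the 18–65 range) |
| `site_offset_sd` | 0.1 | additive per-site, per-feature offset SD |
| `noise_sd` | 0.5 | iid feature noise |
| `n_features` | 100 | GMV-like columns |

Mechanics: every feature has a positive baseline `base_i`; the TIV confound
enters as a global multiplicative scaling `base_i · (1 + leak·ΔTIV/TIV̄)`, so
the "TIV direction" in feature space is the baseline direction.  The
sex-typed pattern is a sparse ±1 vector Gram–Schmidt-orthogonalised against
that direction and normalised, making "signal beyond brain size" an exact,
controllable ground truth: residualising features on TIV perfectly preserves
the pattern's class separation (2·amplitude along a unit direction).  Ages
are uniform on 18–65 and independent between sexes (matching happens
downstream); sites act as additive mean offsets only.

In application samples, transgender subjects draw TIV either from the
distribution of their sex assigned at birth (`sex_matched`, the regime the
source protocol reports) or from a Normal centred midway between the sex
means (`intermediate`); their feature pattern interpolates between sex and
gender identity via `pattern_alignment`.

**Calibration of the defaults.**  The defaults were fixed once, from printed
properties of the study the workflow reproduces, before the acceptance
checks were run:

* the experiment driver's cohort uses `tiv_sd = 66 ml`: the published
  age-matched sample's TIV t statistic (−61.06 at 807 subjects per sex)
  implies a between-sex separation of d ≈ 3.04, i.e. ≈ 66 ml at the 200 ml
  mean gap.  The generator-level default stays at 120 ml, which describes
  overlapping population distributions rather than the heavily age-matched
  study sample;
* `signal_amplitude` and `noise_sd` were chosen so that the TIV-matched
  model's achievable hold-out accuracy lands in the published 87–93% band at
  desk scale (n ≈ 500 training subjects, 100 features), accounting for the
  estimation loss a kernel classifier pays in this regime — the Bayes
  accuracy of the pattern channel alone is Φ(amplitude/noise_sd) ≈ 0.84;
* `scaling_leak = 0.8` keeps the TIV channel recoverable from 100 features
  at the fidelity the published baseline model evidently enjoyed with 77,779
  voxels (a near-noise-free TIV readout); leak compensates for the reduced
  feature count, not for any claim about CAT12 scaling;
* `age_slope = −0.002` yields ≈ 10% total GMV decline across the 18–65 age
  range, a standard ballpark for adult grey-matter loss.

## Experiment driver

One master seed fans out deterministically (via `SeedSequence`) to every
stage: cohort generation, outlier exclusion (|TIV − pool mean| > 3 pool SD),
extraction of two disjoint per-site-quota pools, greedy within-site matching
(AM: age ≤ 1 yr; ATM: age ≤ 1 yr and TIV ≤ 3% of the woman's TIV),
pair-level 80/20 splitting, training, and evaluation on both hold-outs plus
two application scenarios.

Two sampling details depart from naive defaults and are deliberate:

* **pair cap and equalisation** — matched samples are capped at `max_pairs`
  (default 300) and, when AM- and ATM-trained models are compared, both are
  subsampled to the same pair count, mirroring the source design's equal
  sample sizes and keeping the comparison about *composition*, not n;
* **balance-aware reduction of the ATM sample** — greedy tolerance-window
  matching leaves a small systematic residual (the matched man's TIV sits
  slightly above the woman's on average, because male TIV density rises
  across the window).  Left uncorrected, this residual re-introduces a
  sex–TIV association into the nominally matched sample and, amplified
  through the strong TIV direction, lets "matched" models partially exploit
  brain size after all.  The ATM subsample therefore preferentially drops
  the pairs contributing most to the imbalance, restoring the design
  property that the matched sample shows no significant sex difference in
  TIV.  The AM subsample is plain seeded-random.

Greedy one-pass matching (women in ascending age; nearest-age eligible man;
ties by relative TIV difference, then id) was chosen for reproducibility and
auditability; it is not guaranteed maximum-cardinality, and the test suite
checks it reaches ≥ 90% of the brute-force maximum on small instances and
exactly solves instances with a unique perfect matching.  Optimal
(Hungarian) and propensity-score matching are explicit non-goals.

## Problem sizes

The default experiment runs ~8,000-subject pools, 100 features, 300 pairs
per matched sample (480 training subjects after the 80/20 split) and a
25-candidate hyperparameter search.  These sizes were chosen so a full
four-model grid completes in well under a minute per seed on one CPU while
keeping hold-out samples (120 subjects) large enough for stable balanced
accuracies; all of them scale up by config if a closer approach to the
published sample sizes (1,614 per sample, 250 search iterations) is wanted.

## What the synthetic results do and do not show

Passing tests demonstrate that the *machinery* behaves as designed on data
whose generative truth is known: the TIV-naive model exploits the confound
and is flagged by the audit; confound removal eliminates TIV information at
the cost of accuracy; TIV-matching preserves accuracy without bias.  They do
not show anything about real MRI data: the generator's features are
abstract GMV-like columns with a single global TIV coupling, one additive
sex pattern, linear age decline and additive site offsets.  Real voxel data
have spatially structured, heteroscedastic noise, nonlinear TIV scaling
effects, site-by-sequence interactions, and sex differences that are not a
single direction.  Conclusions about the relative merit of matching vs
featurewise removal on real data must come from real data; the package
provides the audited pipeline to do so.

## Known limitations

* The confound remover is linear in TIV; curvilinear TIV effects would leak.
* Platt calibration assumes a sigmoidal score–probability relation; isotonic
  calibration is available by config where that assumption fails.
* The rank-test conventions (continuity correction, tie-corrected variance)
  reproduce the standard normal approximation; exact small-sample p values
  are only used in the test-suite oracle, not exposed.
* Greedy matching yield degrades when the TIV tolerance is small relative to
  the between-sex gap; the driver reports pair counts so infeasible
  configurations fail loudly.
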