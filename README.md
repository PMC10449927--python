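# tivbias

Confound-aware sex classification from grey-matter-volume (GMV) features,
with a built-in audit for brain-size bias.

## The problem

Men have on average a larger total intracranial volume (TIV) than women, so
a classifier trained to predict sex from structural brain features can score
very well by learning brain *size* instead of brain *organisation*.  Such a
model classifies large-brained subjects as male and small-brained subjects
as female — and produces misleading results exactly where it matters, e.g.
when a cisgender-trained classifier is applied to transgender cohorts whose
TIV may fall between the cisgender means.

`tivbias` implements the full comparison workflow for the two standard
remedies:

* **featurewise confound removal** — after PCA, each component score is
  residualised on TIV by OLS, with coefficients learnt on training data only
  and reused on test data (cross-validation-consistent, no leakage);
* **stratification by matching** — the training sample is built from
  woman–man pairs within scanning site with ages ≤ 1 year apart and
  (optionally) TIV ≤ 3% apart, which removes the sex–TIV association from
  the data before any model sees it.

The model grid is {AM, AM+cr, ATM, ATM+cr}: age-matched (AM) vs
age+TIV-matched (ATM) training samples, each without/with confound removal
(+cr).  Every model is a PCA → RBF-SVM pipeline with nested-CV
hyperparameter search over log-uniform C ∈ [1, 1e8], γ ∈ [1e-7, 1], and
Platt-calibrated probabilities.

The **bias audit** partitions each group into subjects classified
congruently vs incongruently with their sex assigned at birth and compares
the two TIV (and total-GMV) distributions with Wilcoxon rank-sum tests
(α = 0.005, effect size η² = z²/N); prediction probabilities of cisgender vs
transgender groups sharing a sex (CW vs TM, CM vs TW) are compared with
pooled-variance t tests (Cohen's d = t·√(1/n₁+1/n₂)).  The verdict is
"bias detected" when misclassifications are TIV-ordered in the biased
direction.

A synthetic multi-site cohort generator (Normal per-sex TIV, a global
TIV-scaling leak, a sex-typed pattern constructed orthogonal to the TIV
direction, age-related GMV decline, site offsets) makes the whole workflow
runnable and testable without any MRI data; see `docs/methods.md` for the
generative model and the calibration of its defaults.

## Worked example

```python
from tivbias.config import ExperimentConfig
from tivbias.orchestrate import run_experiment

bundle = run_experiment(ExperimentConfig(seed=0, run_cv=False))
for model in ("AM", "AM+cr", "ATM", "ATM+cr"):
    cell = bundle.cell(model, "AM_holdout")
    print(f"{model:7s} BA={cell['performance'].balanced_accuracy:.3f} "
          f"verdict={cell['bias'].verdict}")
```

prints (seed 0):

```
AM      BA=0.908  verdict=bias detected
AM+cr   BA=0.575  verdict=no bias detected
ATM     BA=0.892  verdict=no bias detected
ATM+cr  BA=0.658  verdict=no bias detected
```

Read: the TIV-naive AM model is the most accurate on the natural-population
hold-out *and* flagged as biased (its errors are TIV-ordered); featurewise
removal (AM+cr) strips the bias together with most of the accuracy; training
on the TIV-matched sample (ATM) keeps accuracy high with no detectable bias —
the qualitative conclusion the workflow is designed to expose.  On the
TIV-matched hold-out the same run gives AM 0.675 vs ATM 0.875: the biased
model collapses once brain size stops being informative.

The same experiment is available from the shell:

```bash
tivbias run --seed 0 --out results/run0          # full grid + reports
tivbias synth cohort --seed 1 --out-prefix data/pool
tivbias match --in data/pool_subjects.tsv --out data/pairs.tsv --tiv
tivbias train --matched data/pairs.tsv --subjects data/pool_subjects.tsv \
              --features data/pool_features.h5 --confound-removal on \
              --seed 1 --out model.bin
tivbias predict --model model.bin --subjects data/pool_subjects.tsv \
                --features data/pool_features.h5 --out preds.tsv --audit
```

`run` writes Table-style TSVs (performance; rank-sum audits for hold-outs
and application samples), a JSON bundle with full provenance (config hash,
per-stage seeds, versions), calibration and probability-distribution plots,
and a stage log.

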