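# Methods

## The classification problem

A colonoscopy's indication is the clinical reason it was performed:
**diagnostic** (work-up of gastrointestinal signs/symptoms or abnormal
tests), **surveillance** (follow-up of a history of colorectal polyps,
CRC, IBD, or a CRC-related genetic syndrome), or **screening**
(asymptomatic average-risk check).  The package implements two
code-based assignment algorithms, the chart-review reference standard
they are judged against, and the statistics of that judgment, all
exercised on a synthetic cohort generator with known latent truth.

## Hierarchical classifier

The classifier is a precedence rule over code-set categories:

1. **diagnostic** if any diagnostic-class category fires — a GI
   sign/symptom code within its window (default 365 days), a positive
   FIT/FOBT within 365 days, or laboratory iron-deficiency anemia
   within 180 days;
2. else **surveillance** if any history category fires (polyps, CRC,
   IBD, genetic syndrome; unlimited look-back by default — a prior
   polyp remains a prior polyp however old the code);
3. else **screening**.

Window convention: a window of W days is the half-open interval
`[exam_date − W, exam_date)`.  Exam-day codes are excluded by default
because same-day coding usually reflects the procedure itself rather
than its indication; `WindowConfig(include_exam_day=True)` widens the
interval.  An exam without a full year of continuous prior enrollment
(gap tolerance configurable, default 0 days) is *ineligible* and
receives no label rather than a default.

Laboratory iron-deficiency evidence is an explicitly coded IDA flag, an
ICD-9 280.x code, or hemoglobin below a threshold (default 12 g/dL) —
unless every ferritin measured in the same window shows replete iron
stores (≥ 15 ng/mL or a "normal" qualitative result), in which case the
low hemoglobin is not treated as iron deficiency.  A FIT/FOBT lab event
qualifies only with a positive result.

Code matching is exact string comparison on normalized codes (trimmed,
uppercased, decimal retained), with optional per-entry prefix matching
for ICD-9 families.  Code inventories are configuration, not logic: the
bundled registry is an illustrative, synthetic-compatible inventory, so
the classifier logic is unchanged when a production code list is
substituted.

## Screening-probability scorer

The scorer computes η = β₀ + Σⱼ βⱼxⱼ over code-derived features and
reports p = expit(η).  Features default to binary presence within the
term's window (per-term event counts available), which is the common
convention in published claims phenotype models.  Dichotomization uses
the inclusive rule p ≥ c; the boundary choice is documented because it
decides how ties on the ROC staircase fall.

The originally published coefficient set is an external supplementary
file and is not reproduced here; the coefficient file format is the
interface, and `fit_reference_model` produces a working fixture by
L1-penalized (LASSO, liblinear) logistic regression of gold-standard
screening status on one candidate feature per trigger category.  Terms
shrunk exactly to zero are dropped.  This fixture exists to exercise
the machinery; it is not a re-derivation of published coefficients.

## Gold-standard decision tree

From chart-abstraction flags recorded separately per documentation
source (referral, clinic note, procedure report, pre-procedure note)
plus electronic labs:

1. a documented *prior incomplete exam* carries the prior exam's
   indication forward, before any other branch and in every source
   mode, matching the unconditional phrasing of the underlying
   protocol;
2. any of the 17 abstracted GI signs/symptoms in a visible, present
   source — or, in comprehensive mode, a qualifying electronic lab
   (IDA within 180 days, positive FIT/FOBT within 365 days) —
   → **diagnostic**;
3. else any history flag (polyps, CRC, IBD, genetic syndrome) in a
   visible source → **surveillance**;
4. else **screening** if at least one usable source document exists,
   **missing** otherwise.

"Missing" is operationalized as *no source documents present and no
qualifying electronic lab signal*.  Electronic labs participate in
comprehensive mode only; the referral-only and procedure-only modes use
abstracted flags alone.  IBD appears on both sides of the tree by
design: active-disease findings count as diagnostic, history flags as
surveillance.  Because every single-mode-visible finding is also
comprehensively visible, the comprehensive diagnostic rate dominates
each single-source rate — a nesting property the tests check.

## Synthetic cohort generator

The generator emulates the three-center validation setting.  Bundled
profiles carry each center's published margins: gold-standard indication
mixture (232:209:132 with 23/600 missing; 303:190:106 with 1/600;
312:246:38 of 596), the 17 sign/symptom marginal prevalences, and
cosmetic demographics.  Mixtures are normalized over the non-missing
gold rows; record missingness is modeled separately (a "missing" exam
has its latent label drawn but all findings, codes, labs, and sources
suppressed).

Symptoms are sampled independently within diagnostic exams — the
published margins are marginal only, so independence is the declared
simplification — at rates q solved from the fixed point
q = t·(1 − Π(1−q)), where t is the target conditional prevalence.
Conditioning on "at least one finding" (rejection sampling) then yields
cohort-level marginals equal to the configured values in expectation;
the solver's identity is asserted analytically in the tests.
Surveillance exams carry exactly one history type, drawn from a mix
(polyps 0.80, IBD 0.12, CRC 0.05, genetic 0.03) chosen once to reflect
that prior polyps dominate surveillance indications; diagnostic exams
additionally carry a history flag 15% of the time.  2% of exams are
prior-incomplete scenarios whose carried-forward indication equals the
latent label, so carry-forward never contradicts the generative truth.

Exam dates are uniform over 2010–2013; lab events are dated uniformly
inside their look-back windows (FIT/FOBT ≤ 365 days, IDA ≤ 180 days,
optionally tightened by a jitter parameter); history codes are dated
400–1000 days back to genuinely exercise unlimited windows; enrollment
spans start 1100 days before each exam, so every generated exam is
eligible.

Noise is separate from clinical truth: each true trigger emits its code
with probability `code_emission_sensitivity`; spurious trigger codes
arrive Poisson at `spurious_code_rate` per exam; each finding is
documented in one primary source and copied to each other source with
probability 1 − `source_discordance`.  Every random decision consumes
RNG draws unconditionally, so cohorts generated from the same seed at
different emission sensitivities share coupled uniforms: emitted code
sets are *nested* along a sensitivity grid, making degradation curves
deterministic rather than merely monotone in expectation.  The default
noise model is noise-free (the closed-loop identity setting); a
`NoiseModel.realistic()` preset (85% emission, 0.3 spurious codes/exam)
represents deliberately imperfect capture.

What passing tests on this generator do and do not show: closed-loop
recovery demonstrates that the classifier, the gold tree, and the
generator agree on the *semantics* of codes, windows, and the decision
tree — it is a consistency proof of the implementation, not evidence
about real-world accuracy.  Real EHR data add joint symptom structure,
free-text-only findings, coding idiosyncrasies, and cross-system
heterogeneity that the generator deliberately does not model.

## Evaluation statistics

* **Confusion matrices** exclude gold-missing exams first and report
  the excluded count; all denominators derive from the remaining exams.
* **Sensitivity/specificity CIs** are Wald intervals
  p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 1].  This choice reproduces
  the published validation tables' worked examples at two decimal
  places from the printed point estimates and denominators (six cases
  are frozen in the tests), including the boundary case 1.00
  (1.00, 1.00).
* **AUC** is computed both as trapezoidal area under the ROC curve
  (scikit-learn `roc_curve`/`auc`) and as the Mann–Whitney pair
  statistic with half-credit ties; the two are asserted equal on every
  call path.  The 95% CI is DeLong by default (implemented in-package
  via midrank placements; no installed library provides it), with a
  seeded percentile bootstrap (default 2,000 replicates) as an option.
* **Matched-sensitivity comparison**: the cutpoint is the *largest*
  observed score value whose sensitivity under p ≥ c meets the target —
  the operating point maximizing specificity subject to the sensitivity
  floor.  Specificity at that cutpoint is reported with its Wald CI.
  Raising the target can never raise the specificity (ROC
  monotonicity), which the tests verify.

## Pipeline and determinism

`run_pipeline` generates per-center evaluation and training cohorts
from seeds derived deterministically from the run seed, fits the
reference scorer on the training cohort's comprehensive gold labels,
classifies the evaluation cohort with both algorithms, and emits the
report tables, ROC coordinates, and a run log keyed by seed and config
hash (the output directory is excluded from the hash).  No timestamps
enter any output, and floats are written at fixed precision, so
identical seed + config gives byte-identical files.

## Problem sizes

Default problem sizes were chosen as the smallest that make the checks
sharp: closed-loop and degradation checks run at 5,000 exams (binomial
noise ≈ 0.7 percentage points); calibration checks use a 3-Monte-Carlo-SE
band at 5,000; the AUC identity is exercised on 1,000 random cohorts of
up to 50 exams, where brute-force pair enumeration is exact and cheap;
pipeline runs use the study-scale 600-exam centers with 2,000-exam
training cohorts.

## Known limitations

* Symptom co-occurrence is independent given the class; real data show
  correlated symptom clusters.
* The generator writes structured abstraction flags only — no free-text
  notes, hence no NLP pathway to validate.
* The bundled code lists and coefficients are illustrative; results on
  real claims require substituting curated inventories.
* Wald intervals undercover near 0 and 1 at small n; they are used
  because they are what the validation-table convention reproduces, not
  because they are optimal.
* ICD-9-era vocabularies only; no ICD-10 mapping.
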