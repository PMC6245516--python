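# akirisk

Risk of acute kidney injury (AKI) at the moment a patient re-enters the
hospital, estimated from everything the EHR recorded during their *prior*
hospitalizations. AKI is common, costly, and partly preventable, so a
calibrated probability available at hospital re-entry — before any new labs
are drawn — is a useful prior for the admitting provider. This package is
aimed at clinical-ML researchers and biostatisticians who want a fully
testable reference implementation of such a pipeline: because inpatient EHR
extracts cannot be shared, every stage runs against a synthetic cohort
generator with the relevant statistical structure.

## What it implements

**Phenotyping.** A hospitalization is AKI-positive if it carries an ICD-9
584.5–584.9 diagnosis code, or if its serum-creatinine (sCr) series
satisfies a KDIGO delta within the stay:

* sCr(t) / baseline ≥ 1.5 within 7 days, or
* sCr(t) − baseline ≥ 0.3 mg/dL within 48 h,

where the baseline for each measurement is the minimum earlier in-stay
value inside the criterion's window (sliding baseline). Cohort rules remove
stays with age < 18 and stays following an ESRD-coded (585.9) stay without
an intervening renal transplant. A patient with *n* surviving stays yields
*n* − 1 training samples: each rehospitalization is predicted from all
strictly earlier stays.

**Feature compression (s/F/G).** Each stay's irregular, misaligned series
are turned into sequences (*s*), summarized within the stay
(*F*: min/max/mean/var/sum for continuous inputs, counts for categorical
ones), and aggregated across a patient's prior stays
(*G*: min/mean/max/sum/var for labs and abnormal-flag counts; sums for
medications, truncated codes, dispositions, locations, length of stay and
"non-present" code shortfalls *D* − *D*′; max for age; first/last for
demographics). Feature names encode the triple: `mean|max|serum_creatinine`
is the mean over stays of each stay's maximum creatinine. Hierarchical
codes are truncated to 3 leading characters; features with fewer than 100
non-zero, non-missing entries are dropped.

**Modeling.** Every system trains inside a leak-free pipeline on each CV
training fold: grouped 75/25 split; most-frequent-value imputation,
standard scaling (logistic family), learner fit on the 75%; selection by
log loss and Platt sigmoid calibration on the 25%. Variants: gradient
boosting (depth-2 trees) vs L1 logistic regression with fixed
hyperparameters, a highly penalized ~12-feature model, stability-selection
variants, patient-weighted and one-sample-per-patient variants, a
most-recent-stay-only variant, medication-only and clinical-features-only
models, and a permuted-label noise control.

**Evaluation.** Iterated k-fold CV grouped at the patient level (no
patient ever spans train and test), micro/macro metric summaries (ROC AUC,
PR AUC, Brier, log loss), 10-bin reliability curves at hospitalization and
patient level, Bayesian correlated t-tests with a region of practical
equivalence, error regressions over demographic blocks, error by hospital
utilization, leave-one-patient-out coefficient perturbation, and percentile
bootstrap intervals.

## Worked example

`examples/train_and_evaluate.py` generates a 3,000-patient cohort (1,378
training samples at 6.5% prevalence), runs three systems under 2×5 grouped
CV and prints, among others:

```
GBC    roc_auc  micro 0.7218 +- 0.0280   macro 0.7218 +- 0.0181
HPLR1  roc_auc  micro 0.7894 +- 0.0393   macro 0.7894 +- 0.0151
NGBC   roc_auc  micro 0.5231 +- 0.0508   macro 0.5231 +- 0.0055

GBC vs NGBC, ROC AUC posterior (better / equivalent / worse): (1.000, 0.000, 0.000)

HPLR1 keeps 9 features (standardized coefficients):
  max|mean|albumin                         -0.2659
  mean|max|serum_creatinine                +0.2458
  min|max|urea_nitrogen                    +0.1448
  ...
```

Read: the trained pipeline discriminates well above the permuted-label
control (whose ROC AUC sits at chance), the correlated t-test puts all
posterior mass on "better than noise", and the parsimonious model selects
renal-function features with clinically sensible signs — higher urea
nitrogen and creatinine raise predicted risk, higher albumin lowers it.
The other examples (`generate_cohort.py`, `phenotype_labels.py`,
`featurize_history.py`) each demonstrate one stage in isolation.

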