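# Methods

This note records the package's modeling choices, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions — the things a maintainer would otherwise have to
reverse-engineer from the code.

## Phenotyping

AKI is the union of an administrative label (any ICD-9 diagnosis code in
584.5–584.9) and a laboratory label from the KDIGO serum-creatinine
deltas applied within a single stay: a ≥1.5-fold rise within 168 h or a
≥0.3 mg/dL rise within 48 h, windows and thresholds inclusive. The
"sliding baseline" is operationalized as, for each measurement, the
minimum strictly-earlier in-stay value within the relevant window. This
subsumes the first-documented-value rule (early measurements compare
against the first value) and is the standard KDIGO reading; whether a
ratio comparison may also reach back to a post-decrease baseline older
than 48 h is ambiguous in general, and the minimum-in-168h-window reading
is adopted. Detection reports the earliest triggering measurement and
which rule(s) fired there. Rises spanning two rapidly successive stays are
out of scope, as is severity staging.

Cohort rules: stays with age at admission < 18 years are dropped; a stay
is dropped when the same patient has a strictly earlier 585.9-coded stay
with no renal-transplant procedure (default code set: ICD-9-PX 55.69,
configurable) between that stay and the one under consideration. The ESRD
history is evaluated over the patient's full raw admission history, since
the rule concerns what was coded earlier, not whether the earlier stay
itself survived selection. Stays are ordered by admission time, ties
broken by discharge time then admit id. Every admissions row is treated
as a hospitalization (no separate "under observation" status).

## Feature extraction

Within-stay summaries use sample variance (denominator *n* − 1) with the
variance of a singleton defined as 0, because single-measurement stays
are common and the statistic must exist there. Length of stay is in
fractional days. Missingness is preserved: a lab never measured in a stay
yields missing within-stay statistics, the across-stay aggregation runs
over observed stays only, and imputation happens exclusively inside the
modeling pipeline — so no information about the imputation corpus can
leak into featurization. Counts (medications, truncated codes,
dispositions, location visits) are genuine zeros when the event did not
occur. Location visits are counted per visit, not per distinct location.

Codes from all four systems (ICD-9 diagnoses and procedures, CPT-4, DRG)
are truncated to the same precision (default 3 leading characters, dot
stripped). "Non-present" shortfall features *D* − *D*′ are built for
diagnoses, CPT-4 procedures and DRGs; the corpus maximum *D* is learned
from training data only. Because the per-sample feature table already
aggregates over stays, each sample carries helper columns (per-stay
maximum and total code counts, number of prior stays) from which the
fold-level transform computes the shortfall sum exactly; helper columns
never enter a model. The sparsity filter (default: fewer than 100
non-zero, non-missing entries) runs once on the full table before CV — it
is response-independent dimensionality reduction. At desk scale the
threshold should be scaled with the corpus (the tests use 15–100).

The condensed clinical feature set is maximum age plus three
history indicators (renal insufficiency = any prior AKI label or 584/585
code; diabetes = 250.x; heart failure = 428.x). These composites are kept
out of the full feature set so the main models never see them.

## Modeling

All transforms are fit on the training side only. Imputation uses the
per-feature most frequent value with ties broken toward the smaller value
(determinism); a feature entirely missing in training imputes 0 with a
warning. Scaling (logistic family only) uses the training mean and
population standard deviation (`ddof=0`), zero-variance features divide
by 1. The Anscombe transform `2*sqrt(x + 3/8)` applies to count and
categorical-derived columns, after imputation and before scaling;
tree-based learners are unaffected by monotone transforms and skip it.

Fixed hyperparameters: gradient boosting with max depth 2, min samples
per split 150, min samples per leaf 100 (other settings at scikit-learn
defaults); L1 logistic regression at inverse penalty C = 2e-3 (highly
penalized variant 2e-4, aiming at a model of roughly a dozen features);
stability selection at C1 = 0.5 / C2 = 1 (highly penalized: C1 = 0.2),
sampling fraction 0.75, 50 resamples; clinical-features model: ridge
logistic at C = 1000 (effectively unpenalized). Logistic-family models
use prevalence-balanced class weights, n/(2·n_c).

Those C values were fixed for a training fold of ~67,500 samples, and
liblinear's objective multiplies the *summed* loss by C, so the same C on
a small corpus is a much stronger per-sample penalty. `VariantConfig.
c_reference_n` (default: off) rescales the effective C by
`c_reference_n / n_fit` to keep the per-sample penalty at the intended
operating point; desk-scale runs in the tests, examples and acceptance
script set it to 67,510.

Each training fold is split 75/25 grouped by patient. Candidate learners
(gradient boosting and L1 logistic for the main and noise variants; the
single named learner otherwise) fit on the 75%; the candidate with the
lowest log loss on the 25% is selected and Platt-calibrated on that same
25%. The alternative reading — selecting candidates by an inner CV — is
not implemented; the 25%-split reading is the package's single documented
behavior. Platt calibration maximizes the likelihood of
`1/(1 + exp(A·f + B))` with A constrained non-positive, which guarantees
a monotone non-decreasing calibrated predictor while containing the plain
sigmoid, so calibrated log loss never exceeds the uncalibrated mapping on
the calibration split; a single-class calibration split falls back to the
identity mapping with a warning. Note that with balanced class weights
the logistic candidates' raw probabilities are biased upward at low
prevalence, which systematically disadvantages them in pre-calibration
log-loss selection — visible in the tests, and inherent to this design.

Stability selection subsamples ⌊0.75 · n_patients⌋ patients (grouped,
without replacement) per resample; randomization is via subsampling only.
The keep threshold on selection frequency is not prescribed anywhere;
default 0.6, exposed in the config.

## Evaluation

Cross-validation is grouped at the patient level with uniform-random
patient-to-fold assignment per seed; train/test patient disjointness is
asserted on every fold. Micro summaries are mean ± sd over all
iteration×fold values (sd over folds, not samples); macro over
per-iteration means. Reliability curves use 10 equal-width bins on [0, 1]
with empty bins reported at count 0. Patient-level aggregation
macro-averages predictions over iterations first, then averages observed
and predicted risk per patient; its reliability curve uses only patients
whose mean observed risk is exactly 0 or 1, where an observed frequency
is well defined.

The Bayesian correlated t-test places a Student-t posterior on the mean
paired-fold metric difference: ν = n − 1, location x̄, squared scale
(1/n + ρ/(1 − ρ)) s² with ρ = 1/k, the standard test-fraction correlation
for k-fold CV. Reported is the posterior mass below, inside and above a
region of practical equivalence of half-width r/2 (defaults r = 0.01 for
ROC/PR AUC, 0.001 for Brier). A degenerate s = 0 posterior puts all mass
on x̄'s region. Error regressions are lasso fits of |error| on one
covariate block per outcome stratum under the same grouped-CV scheme,
with the penalty chosen on one grouped split by the
train-approximates-validation gap heuristic from a small grid; bootstrap
intervals are percentile intervals of the mean (default 1,000 resamples;
coverage verified at 95% ± 3 points in simulation).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline needs, not
any real population. Per patient: a latent frailty z ~ N(0,1) drives
chronic conditions (CKD, diabetes, heart failure) and standardized lab
latents (urea nitrogen up with frailty; albumin and hemoglobin down);
stays per patient follow a truncated geometric on {1..20} tuned so
P(≥2 stays) = 0.32; admission gaps are exponential (mean 60 days) and
stay lengths lognormal (median 3.5 days). Per stay, the true-AKI
indicator is Bernoulli with logit `intercept + x·β` over age (+0.5/sd),
prior AKI (+1.0), CKD (+0.9), diabetes (+0.35), heart failure (+0.5),
and the urea (+0.7), albumin (−0.5) and hemoglobin (−0.4) latents; the
intercept is calibrated by bisection so the realized true prevalence
among rehospitalization stays is 0.062. True AKI plants a
KDIGO-triggering creatinine trajectory with probability 0.8 and earns a
584.x code with probability 0.65; non-AKI stays get a false 584.x code
with probability 0.005. Lab observation times are homogeneous Poisson
within the stay (the real lab-sampling process is unknown;
this is an assumption), with creatinine/urea sampling inflated 1.8× under
true AKI — the informative-sampling signal the count features exploit.
Measurement noise is multiplicative lognormal around patient baselines;
creatinine additionally uses a stay-level shift with small within-stay
jitter, since white per-measurement noise would fake KDIGO deltas at
clinically implausible rates in high-baseline patients.

What the generator does **not** emulate: real demographic or code
frequency distributions, medication dosing patterns, temporal drift,
care-pattern feedback (treatment suppressing the outcome in high-risk
patients), or cross-stay AKI evolution. Passing tests therefore show that
the pipeline recovers structure it was designed to recover under its own
assumptions — not that any real-data performance number transfers.

## Desk-scale problem sizes

The reference experiment design (50 iterations of 5-fold CV on ~90,000
samples) is scaled down so everything runs in minutes on one CPU: the
acceptance checks use a 9,000-patient cohort (~4,200 training samples at
6.2% prevalence) with 5 iterations of grouped 5-fold CV, chosen so the
Monte-Carlo standard error of a micro-averaged ROC AUC (~0.01 for the
noise control) is small against the tolerances being checked. At much
smaller cohorts (~1,000 samples) the fixed boosting leaf size (100) is a
fifth of a training fold and discrimination degrades substantially; the
end-to-end recovery checks therefore run at the 9,000-patient size.
Examples use 400–3,000 patients. The stability-selection resample count
(50) and bootstrap default (1,000; the reference analysis used 10,000)
follow the same principle.

## Known limitations

The recurrent-network variant of the reference design is out of scope, as
is any hyperparameter search (all HP are fixed; only overridable via
config). The error-regression penalty heuristic is deliberately simple
(one grouped split, small grid). The coefficient-perturbation analysis
refits once per patient and is meant for desk-scale cohorts. Calendar
semantics are deliberately absent: all timestamps are continuous hours
from an epoch, and day-of-week style features would have to be derived
modulo 168 h.
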