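"""Generate a synthetic EHR cohort and inspect its structure.

Builds a 2,000-patient cohort with the study conditions (about a third of
patients rehospitalized, ~6% AKI prevalence among training samples), writes
it as CSV files, and prints the realized cohort statistics next to their
targets.
"""

import numpy as np

import akirisk as ak

config = ak.GeneratorConfig(n_patients=2000, seed=7)
ehr = ak.generate_cohort(config)
ak.write_ehr_csv(ehr, "scratch/example_cohort", timestamps="hours")

n_hosp = len(ehr.admissions)
per_patient = ehr.admissions.groupby("patient_id").size()
samples, hosp_by_id, exclusions = ak.cohort_samples(ehr)
labels = np.array([s.label for s in samples])

print(f"patients:                 {config.n_patients}")
print(f"hospitalizations:         {n_hosp}")
print(f"rehospitalized fraction:  {(per_patient >= 2).mean():.3f}  (target 0.32)")
print(f"training samples (n-1):   {len(samples)}")
print(f"AKI prevalence (labels):  {labels.mean():.4f}  (target 0.062)")
print(f"excluded stays:           {len(exclusions)}")
print("\nThe four linked tables plus ground truth were written to "
      "scratch/example_cohort/. Each training sample predicts AKI during "
      "one rehospitalization from all of that patient's earlier stays.")
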