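"""Compress a patient's prior hospitalizations into one feature vector.

Demonstrates the s/F/G scheme: within-stay summaries (min/max/mean/var/sum
for labs, counts for categorical inputs) aggregated across stays with
per-category rules, plus code truncation and non-present counts.
"""

import numpy as np

import akirisk as ak

ehr = ak.generate_cohort(ak.GeneratorConfig(n_patients=400, seed=21))
samples, hosp_by_id, _ = ak.cohort_samples(ehr)
fm = ak.featurize_corpus(samples, hosp_by_id)

# pick a sample with at least two prior stays
sample = next(s for s in samples if len(s.prior_admit_ids) >= 2)
row = fm.X.loc[sample.target_admit_id]

print(f"sample: target {sample.target_admit_id}, "
      f"{len(sample.prior_admit_ids)} prior stays, label={sample.label}")
print(f"corpus: {fm.X.shape[0]} samples x {fm.X.shape[1]} features\n")

show = [
    "max|value|age",
    "mean|max|serum_creatinine",
    "mean|mean|urea_nitrogen",
    "sum|count|dx:584",
    "sum|count|dx:585",
]
for name in show:
    if name in row.index:
        g, f, base = ak.features.parse_feature_name(name)
        print(f"  {name:32s} = {row[name]:8.3f}   (G={g}, F={f}, base={base})")

X2, _, state = ak.add_nonpresent_features(fm.X, fm.schema)
print(f"\nnon-present diagnosis shortfall for this sample: "
      f"{X2.loc[sample.target_admit_id, 'sum|count|nonpresent:dx']:.0f} "
      f"(corpus max per-stay dx count D = {state['dx']})")

Xf, kept = ak.filter_sparse(fm.X, threshold=20, schema=fm.schema)
print(f"sparsity filter at 20 non-zero/non-missing entries: "
      f"{fm.X.shape[1]} -> {len(kept)} features")
print("\nFeature names read '<G>|<F>|<base>': e.g. mean|max|serum_creatinine "
      "is the mean over prior stays of each stay's maximum creatinine.")
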