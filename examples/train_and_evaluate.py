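"""Train calibrated risk models and evaluate them under grouped CV.

Runs the main gradient-boosting pipeline, the parsimonious highly
penalized logistic regression, and the permuted-label noise control on a
synthetic cohort; prints micro/macro metric summaries, a Bayesian
correlated t-test comparison, and the parsimonious model's coefficients.

Takes a few minutes on one CPU.
"""

import numpy as np

import akirisk as ak

REFERENCE_TRAIN_FOLD_N = 67_510  # training-fold size the fixed L1 penalties assume

print("generating a 3,000-patient cohort ...")
ehr = ak.generate_cohort(ak.GeneratorConfig(n_patients=3000, seed=5))
samples, hosp_by_id, _ = ak.cohort_samples(ehr)
fm = ak.featurize_corpus(samples, hosp_by_id)
fm.X, _ = ak.filter_sparse(fm.X, threshold=50, schema=fm.schema)
print(f"{len(samples)} training samples, {fm.X.shape[1]} features, "
      f"prevalence {fm.y.mean():.3f}\n")

results = {}
for variant in ("GBC", "HPLR1", "NGBC"):
    cfg = ak.VariantConfig(variant=variant, c_reference_n=REFERENCE_TRAIN_FOLD_N)
    results[variant] = ak.run_cv(fm, cfg, iterations=2, k=5, base_seed=3)
    for metric in ("roc_auc", "pr_auc", "brier"):
        s = ak.micro_macro_summary(results[variant], metric)
        print(f"{variant:6s} {metric:8s} micro {s.micro_mean:.4f} +- "
              f"{s.micro_sd:.4f}   macro {s.macro_mean:.4f} +- {s.macro_sd:.4f}")
    print()

post = ak.compare_systems(results["GBC"], results["NGBC"], "roc_auc",
                          k=5, rope=0.01)
print("GBC vs NGBC, ROC AUC posterior (better / equivalent / worse): "
      f"({post.p_right:.3f}, {post.p_rope:.3f}, {post.p_left:.3f})")
print("A posterior mass near 1 in the first slot says the trained system "
      "beats the permuted-label control by more than the 0.01 ROPE.\n")

cfg = ak.VariantConfig(variant="HPLR1", c_reference_n=REFERENCE_TRAIN_FOLD_N, seed=0)
model = ak.fit_pipeline(fm.X, fm.y, fm.groups, fm.schema, cfg)
coefs = model.coefficients
nz = coefs[coefs.abs() > 1e-10].sort_values(key=np.abs, ascending=False)
print(f"HPLR1 keeps {len(nz)} features (standardized coefficients):")
for name, v in nz.items():
    print(f"  {name:40s} {v:+.4f}")
print("\nPositive coefficients raise the predicted AKI risk (age, prior "
      "AKI codes, urea nitrogen); negative ones lower it (albumin, "
      "hemoglobin).")
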