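"""Simulate a study-like multimorbid cohort and look at its structure.

The generator draws four age strata whose sizes, demographics, latent
cluster structure and outcome levels mirror a large English primary-care
multimorbidity cohort (scaled down by a configurable factor).
"""

from mmclust import default_truth, is_multimorbid, simulate_cohort, stratify_by_age

cohort, truth = simulate_cohort(default_truth(scale=100, seed=0))

print(f"cohort size: {cohort.n} patients, {len(cohort.condition_registry)} conditions")
print(f"multimorbid (2+ conditions): {100 * is_multimorbid(cohort).mean():.1f}%")
for label, sub in stratify_by_age(cohort).items():
    print(f"  stratum {label}: {sub.n} patients")
print("\nfirst rows:")
print(cohort.data.iloc[:3, :8].to_string(index=False))
# Most patients carry 2+ chronic conditions because the generating classes
# mirror multimorbidity clusters; the stratum sizes are the study's scaled
# by 1/100. The true class labels live in the separate `truth` table.
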