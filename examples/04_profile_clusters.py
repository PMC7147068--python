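"""Label clusters by their most distinctive conditions.

After fitting, each cluster is profiled by within-cluster condition
prevalences; its 'key conditions' are the three whose prevalence most
exceeds the age-stratum prevalence.
"""

from mmclust import (
    build_profiles,
    default_truth,
    filter_multimorbid,
    fit_em,
    simulate_cohort,
    stratify_by_age,
)

cohort, _ = simulate_cohort(default_truth(scale=20, seed=1))
stratum = stratify_by_age(filter_multimorbid(cohort))["85+"]
fit = fit_em(stratum.condition_matrix(), K=3, n_restarts=10, seed=3)

for p in build_profiles(fit.assignment, stratum, stratum_label="85+"):
    print(f"cluster {p.cluster_id}: {p.size} patients ({p.pct_of_stratum:.0f}%)")
    print(f"   label: {p.label()}")
    print(f"   morbidities median {p.summaries['morbidity_median']:.0f}, "
          f"female {p.summaries['pct_female']:.0f}%")
# Labels read 'lead (prev%) | key2 (prev%), key3 (prev%)': e.g. a
# hypertension-led cluster versus a cardiac (CHD/heart failure) cluster —
# the within-cluster prevalences say how concentrated each condition is.
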