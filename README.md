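# mmclust

Age-stratified clustering of multimorbid patients from binary long-term-
condition records, with hold-out validation and outcome models.

## The problem

Multimorbidity — living with two or more long-term conditions — is common,
heterogeneous, and strongly associated with health-service use and
mortality. Grouping *patients* (not diseases) by their patterns of
co-existing conditions yields clusters that can be profiled, validated and
related to outcomes, which is useful for anyone designing services around
people rather than single diseases. `mmclust` implements that analysis as a
tested, reusable Python library for epidemiologists and health-services
researchers working with primary-care extracts (or, out of the box, with
its own synthetic cohorts).

## The model

Patients carry J = 38 binary condition flags **y**ᵢ ∈ {0,1}ᴶ. Within each
age stratum (18–44, 45–64, 65–84, 85+), a latent class model assumes each
patient belongs to one of K unobserved classes with mixing proportions
π = (π₁…π_K); given class k the conditions are independent Bernoulli draws
with item-response probabilities ρ_kj:

    ℓ = Σᵢ ln Σₖ πₖ Πⱼ ρₖⱼ^yᵢⱼ (1−ρₖⱼ)^(1−yᵢⱼ)

maximised by EM with multiple random restarts. K is chosen from BIC,
sample-size-adjusted BIC (aBIC = −2ℓ + p·ln((N+2)/24)), a parametric
bootstrap likelihood-ratio test, and the relative entropy
E = 1 + Σᵢₖ p̂ᵢₖ ln p̂ᵢₖ / (N ln K) of the posterior classification.
Patients take their modal class; clusters are labelled by the three
conditions whose within-cluster prevalence most exceeds the stratum
prevalence. Stability is assessed by refitting on a held-out 20% split and
matching clusters by smallest Jensen–Shannon distance and highest Pearson
correlation between prevalence profiles. Finally, log-link count GLMs
(negative binomial or Poisson) give adjusted incidence rate ratios (aIRR)
for GP consultations, hospitalisations and regular medications, and
logistic GLMs give odds ratios (OR) for 2- and 5-year mortality, against
the lowest-impact reference cluster, adjusted for gender, deprivation
(IMD), smoking, BMI and age.

A first-class synthetic-cohort generator simulates all of this with known
ground truth (including a built-in four-stratum study-like design), so the
whole pipeline is testable without access to licensed health records.

## Worked example

```python
from mmclust import (default_truth, simulate_cohort, filter_multimorbid,
                     stratify_by_age, select_k)

cohort, truth = simulate_cohort(default_truth(scale=20, seed=1))
stratum = stratify_by_age(filter_multimorbid(cohort))["65-84"]
sel = select_k(stratum.condition_matrix(), range(1, 6), seed=2,
               n_restarts=5, tol=1e-7)
print(sel.table[["K", "bic", "abic", "entropy"]].round(1))
print("chosen K =", sel.chosen_K)
```

prints

```
 K    loglik      bic     abic  entropy
 1 -27243.05 54779.56 54658.83     1.00
 2 -26977.74 54550.14 54305.49     0.89
 3 -26879.96 54655.76 54287.21     0.76
 4 -26783.20 54763.42 54270.96     0.80
 5 -26747.98 54994.16 54377.79     0.73

chosen K = 4
```

on a ~2,260-patient multimorbid stratum: BIC (harsher penalty) bottoms out
at K=2 while aBIC keeps improving to K=4–5; among the candidates whose
classification entropy clears the 0.8 quality floor (K ∈ {1, 2, 4}), K=4
has the lowest aBIC and is chosen. The full table is always emitted so the
statistics can be weighed alongside clinical judgement. Profiling the
fitted clusters (`examples/04_profile_clusters.py`, 85+ stratum) then
prints labels such as

```
cluster 2: 42 patients (7%)
   label: coronary_heart_disease (76%) | atrial_fibrillation (74%), heart_failure (64%)
```

i.e. a small cardiac cluster whose members nearly all carry coronary heart
disease, atrial fibrillation and heart failure — far above those
conditions' prevalence in the stratum.

The `examples/` directory walks through each capability: simulation,
descriptive tables and independence tests, K selection, cluster labelling,
hold-out validation, outcome models, and the end-to-end pipeline
(`mmclust run` on the command line).

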