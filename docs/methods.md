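# Methods

This note documents the statistical model, the defaults and why they are
set where they are, the synthetic-data generator's scope, and the
numerical and design choices made where the design was genuinely open.

## Latent class model and estimation

Each patient in an age stratum contributes a binary vector of J = 38
long-term-condition flags. The model is a finite mixture of K product-
Bernoulli components: mixing proportions π on the simplex and item-
response probabilities ρ ∈ [ε, 1−ε]^{K×J}. Conditions are present or not
by definition of the extract, so no missing-data machinery is used in the
clustering itself.

Estimation is EM with multiple random restarts:

* **Initialisation**: π ~ Dirichlet(1,…,1), ρ ~ Uniform(0.05, 0.95) per
  restart. Default 20 restarts for final fits; K-scans use 5 (the scan
  only needs the likelihood surface ranked, and the chosen K is refit
  implicitly by keeping the scan's best fit).
* **Convergence**: relative log-likelihood change < 1e-8 (1e-7 in scans),
  capped at 1000 iterations. Within every run the log-likelihood is
  *asserted* non-decreasing (tolerance 1e-9 relative, absorbing float
  round-off); a decrease is a bug, not a warning.
* **Boundary handling**: ρ is clamped to [1e-6, 1−1e-6] so saturated
  items cannot produce log(0). An M-step class with zero posterior mass is
  re-seeded uniformly with a warning.
* **Exactness/speed**: duplicate response patterns are collapsed to
  unique rows with multiplicities before EM; the weighted updates are
  algebraically identical to the row-wise ones. All densities are
  computed in log space with log-sum-exp over classes.
* **Label switching**: classes are relabelled in descending π after
  fitting, so cluster identities are stable across runs and usable
  downstream. Modal assignment breaks posterior ties toward the lowest
  class index.

## Choosing K

For each candidate K the selection table reports log-likelihood, p =
(K−1) + K·J free parameters, BIC = −2ℓ + p ln N, aBIC = −2ℓ +
p ln((N+2)/24), and the relative entropy E = 1 + Σᵢₖ pᵢₖ ln pᵢₖ /(N ln K)
(E ≡ 1 for K = 1; 1 = perfectly separated posteriors, 0 = uninformative).
The default decision rule — minimise aBIC among fits with E ≥ 0.8 —
encodes "best penalised fit subject to acceptable classification quality".
The entropy floor of 0.8 is a conventional adequacy threshold for
classification quality; it is configurable, and when no K clears it the
global aBIC minimiser is chosen and flagged. The full table is always
emitted because the final call in applied work combines these statistics
with clinical judgement, which no automatic rule replaces.

The likelihood-ratio test of K vs K+1 is implemented as a **parametric
bootstrap** (mixtures violate the chi-square regularity conditions): B
datasets are simulated from the fitted null, both models are refit on
each, and p = (1 + #{boot ≥ observed})/(B+1). B defaults to 19 for tests
and 99 for analysis runs. The (K+1)-class fit always includes one
warm-start initialisation obtained by splitting the null's largest class,
which (EM being monotone) guarantees ℓ_alt ≥ ℓ_null and hence a
non-negative observed statistic.

## Profiling and labelling

Cluster profiles are **modal-assignment** within-cluster prevalences (not
posterior-weighted), matching the convention of allocating each patient to
a single cluster before any description. Distinctiveness of condition j in
cluster k is within-prevalence minus stratum prevalence; the three most
distinctive conditions with positive distinctiveness label the cluster
(ties: higher within-prevalence, then registry order). Because a lead
condition could alternatively be ranked by raw within-cluster prevalence,
the profile also records that alternative lead whenever it differs.
Displayed percentages are rounded to integers; underlying values are kept
at full precision.

## Hold-out validation

The multimorbid cohort is split 80/20 by stratified sampling within age
strata (train size = floor(0.8 × stratum size), seeded). The test split is
refit at the training K, and each test cluster is matched to a training
cluster twice: by smallest Jensen–Shannon distance between profiles
normalised to probability distributions (base-2 logs, so the distance is
bounded by 1 and the "smallest" criterion is scale-free) and by highest
Pearson correlation on the raw prevalences. Matching is per test cluster —
many-to-one is allowed, since the smaller test split may not reproduce
every training cluster. When the two criteria disagree the disagreement is
reported, not resolved. Entropy in both splits is recorded; similar values
are further stability evidence.

## Outcome models

Complete cases only (records missing smoking or BMI dropped; a warning
fires when the exclusion reaches 5%). The reference cluster is the one
with the smallest rank-sum across mean GP consultations, mean
hospitalisations, mean regular medications and 5-year mortality (ties to
the larger cluster); a configuration flag instead uses the non-multimorbid
group as reference for sensitivity analyses. The design matrix uses
indicator coding for cluster (reference omitted), gender (female
reference) and smoking (never-smoker reference), IMD as a single ordinal
1–5 term (indicator coding available), and BMI and age continuous.

Counts use a log-link negative binomial GLM by default — one-year
consultation and prescription counts are overdispersed — with the
dispersion α (var = μ + αμ²) estimated by outer maximisation of the
profile likelihood over log α ∈ [log 1e-6, log 50] around the inner IRLS
fit; Poisson is available as the equidispersed special case and the two
coincide as α → 0. Mortality uses logistic GLMs, with complete/quasi-
separation detected (statsmodels' perfect-prediction signal plus fitted
probabilities at machine bounds) and reported as an error naming suspect
columns. Intervals are Wald 95% throughout, matching standard aIRR [95%
CI] reporting; exponentiated coefficients are aIRRs (counts) or ORs
(mortality). None of these associations is causal.

## Synthetic cohorts

The generator emulates the structure of an age-stratified primary-care
multimorbidity extract: per stratum, class labels are drawn from π, then
conditions from ρ; demographics (gender, IMD quintile, smoking, BMI) from
stratum-specific categorical/normal distributions; smoking/BMI missingness
injected at stratum rates; ages uniform over the stratum's integer range
(adequate because the pipeline uses age only as stratifier and covariate).
Outcomes are generated from the same families the models fit: negative
binomial (or Poisson) counts with log-link linear predictors in class and
covariates, logistic 2-year mortality, and 5-year mortality generated
hierarchically — death by year 2 implies death by year 5; survivors draw a
conditional year-2-to-5 Bernoulli — so the monotonicity constraint holds
by construction. True class labels live in a separate truth table, never
in the cohort file.

`default_truth()` encodes the study-like conditions: four strata whose
sizes scale from (15,306, 36,097, 49,494, 12,314); K = (5, 5, 6, 4)
classes whose shares and lead/key-condition prevalences follow the
published cluster descriptions, over a background prevalence rising with
age (0.04 → 0.10); demographic mixes, BMI distributions and missingness
rates per the published stratum characteristics; and count/mortality
levels per published cluster outcome tables (count dispersions 0.35/1.0/
0.6 for consultations/hospitalisations/medications, chosen as typical
overdispersion for such data). The generator does **not** emulate disease-
specific epidemiology, calendar-time incidence, condition accrual
sequences, or within-cluster outcome heterogeneity beyond the covariates —
so passing tests demonstrate correctness of the estimators under the
stated generating model, not performance on real extracts.

## Problem sizes used in tests and the acceptance script

Parameter-recovery studies use N = 5,000 patients, J = 20 conditions and
three classes with block profiles separated by 0.65; K-selection is
scanned over K = 1…6 with 5 restarts in 20 (tests) or 10 (script)
replicates. GLM recovery uses n = 5,000 with a planted aIRR of 1.5
(negative binomial, α = 0.4) and OR of 2.0 over 200 replicates. The grid-
search oracle for EM runs at N = 50, J = 3, K = 2 with step 0.05 (the
float32 scan locates the optimum, which is then re-evaluated in float64).
End-to-end runs use the study design scaled by 1/100 (~1,130 patients) for
determinism checks and a separated four-stratum design (~10,000 patients,
K = 2, 3, 3, 2) for K-recovery — with five or six overlapping generating
classes per stratum, K-recovery at a few thousand patients is not
information-theoretically reliable, which is itself visible in the
selection tables the pipeline emits.

## Known limitations

* The selection rule is a documented stand-in for a judgement-based
  process; different weightings of BIC/aBIC/LRT/entropy are legitimate.
* Wald intervals (not profile likelihood) and a point estimate of the NB
  dispersion: interval coverage for the dispersion itself is not provided.
* The clusterer handles binary indicators only (no polytomous items, no
  covariate-dependent class membership).
* Cross-database external validation is out of scope; the hold-out split
  shares every bias of the source cohort.
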