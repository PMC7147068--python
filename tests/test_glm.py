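"""Outcome models: complete-case filtering, reference-cluster rule,
design construction, and GLM closed-form checks."""

import numpy as np
import pandas as pd
import pytest

from mmclust import (
    LCAParameters,
    OutcomeCoefficients,
    SimulationTruth,
    StratumSpec,
    build_design,
    choose_reference_cluster,
    cluster_outcome_summary,
    complete_case_filter,
    fit_count_glm,
    fit_mortality_glm,
    simulate_cohort,
)
from mmclust.glm import GLMError
from test_profiling import _cohort


def test_complete_case_filter_identity_without_missingness():
    c = _cohort([[1, 1]] * 10)
    out, report = complete_case_filter(c)
    assert out.n == 10 and report["n_excluded"] == 0


def test_complete_case_filter_counts_and_threshold_warning():
    bmi = [27.0] * 19 + [np.nan]
    c = _cohort([[1, 1]] * 20, bmi=bmi)
    with pytest.warns(RuntimeWarning, match="5"):
        out, report = complete_case_filter(c)
    assert out.n == 19
    assert report["pct_excluded"] == pytest.approx(5.0)

    c2 = _cohort([[1, 1]] * 10, smoking=["never"] * 9 + [np.nan])
    with pytest.warns(RuntimeWarning):
        _, r2 = complete_case_filter(c2)
    assert r2["pct_excluded"] == pytest.approx(10.0)


def _summary(rows):
    return pd.DataFrame(rows)


def test_reference_cluster_lowest_on_all_outcomes():
    s = _summary([
        {"cluster_id": 0, "n": 50, "gp_consults_mean": 10, "hospitalisations_mean": 1,
         "regular_meds_mean": 4, "mortality_5yr_pct": 10},
        {"cluster_id": 1, "n": 60, "gp_consults_mean": 5, "hospitalisations_mean": 0.5,
         "regular_meds_mean": 2, "mortality_5yr_pct": 2},
    ])
    assert choose_reference_cluster(s) == 1


def test_reference_cluster_rank_sum_tie_goes_to_larger_cluster():
    s = _summary([
        {"cluster_id": 0, "n": 100, "gp_consults_mean": 5, "hospitalisations_mean": 1,
         "regular_meds_mean": 2, "mortality_5yr_pct": 10},
        {"cluster_id": 1, "n": 50, "gp_consults_mean": 10, "hospitalisations_mean": 0.5,
         "regular_meds_mean": 4, "mortality_5yr_pct": 2},
    ])
    assert choose_reference_cluster(s) == 0


def test_reference_cluster_recovers_planted_low_use_class():
    """A three-class design with one planted low-impact class: the rule
    picks it in >= 19/20 seeded replicates."""
    coeffs = {
        "gp_consults": OutcomeCoefficients(np.log(10), (0.4, 0.0, 0.6)),
        "hospitalisations": OutcomeCoefficients(np.log(0.6), (0.5, 0.0, 0.7)),
        "regular_meds": OutcomeCoefficients(np.log(3), (0.5, 0.0, 0.6)),
        "died_2yr": OutcomeCoefficients(-3.0, (0.7, 0.0, 1.0)),
        "died_5yr": OutcomeCoefficients(-2.2, (0.7, 0.0, 1.0)),
    }
    params = LCAParameters(pi=np.array([0.4, 0.35, 0.25]),
                           rho=np.full((3, 6), 0.5))
    hits = 0
    for r in range(20):
        spec = StratumSpec(label="65-84", n_patients=800, age_range=(65, 84),
                           params=params, outcomes=coeffs,
                           dispersion={"gp_consults": 0.4})
        cohort, truth = simulate_cohort(SimulationTruth(strata=[spec], seed=500 + r))
        s = cluster_outcome_summary(truth["true_class"].to_numpy(), cohort)
        hits += choose_reference_cluster(s) == 1
    assert hits >= 19


def test_design_reference_patient_has_zero_indicators():
    c = _cohort([[1, 1]] * 4, gender=["F"] * 4, smoking=["never"] * 4)
    X = build_design(c, np.array([0, 0, 1, 1]), reference_cluster=0)
    ref_row = X.iloc[0]
    assert ref_row["cluster_1"] == 0 and ref_row["gender_M"] == 0
    assert ref_row["smoking_current"] == 0 and ref_row["smoking_ex"] == 0
    # column bookkeeping: intercept + (K-1) + gender + 2 smoking + imd + bmi + age
    assert X.shape[1] == 1 + 1 + 1 + 2 + 1 + 1 + 1


def test_design_full_rank_on_synthetic_cohort(two_class_params):
    from conftest import _stratum_outcomes

    spec = StratumSpec(label="45-64", n_patients=500, age_range=(45, 64),
                       params=two_class_params, outcomes=_stratum_outcomes(2)[0])
    cohort, truth = simulate_cohort(SimulationTruth(strata=[spec], seed=1))
    X = build_design(cohort, truth["true_class"].to_numpy(), reference_cluster=0)
    assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]


def test_design_rejects_incomplete_cases():
    c = _cohort([[1, 1]] * 3, bmi=[27.0, np.nan, 25.0])
    with pytest.raises(GLMError, match="complete"):
        build_design(c, np.array([0, 0, 1]), reference_cluster=0)


def test_two_group_poisson_reproduces_ratio_of_means():
    X = pd.DataFrame({"intercept": 1.0, "cluster_1": [0.0] * 50 + [1.0] * 50})
    y = np.array([2] * 50 + [4] * 50)
    r = fit_count_glm(y, X, family="poisson")
    assert r.table.set_index("term").loc["cluster_1", "ratio"] == pytest.approx(2.0, abs=1e-8)
    t = r.table.set_index("term")
    assert (t["ratio_ci_low"] <= t["ratio"]).all() and (t["ratio"] <= t["ratio_ci_high"]).all()


def test_identical_counts_give_unit_rate_ratio():
    X = pd.DataFrame({"intercept": 1.0, "cluster_1": [0.0] * 20 + [1.0] * 20})
    y = np.full(40, 3)
    r = fit_count_glm(y, X, family="poisson")
    assert r.table.set_index("term").loc["cluster_1", "ratio"] == pytest.approx(1.0, abs=1e-8)


def test_nb_and_poisson_agree_on_equidispersed_data():
    rng = np.random.default_rng(3)
    X = pd.DataFrame({"intercept": 1.0, "g": rng.integers(0, 2, 2000).astype(float)})
    y = rng.poisson(np.exp(1.0 + 0.4 * X["g"]))
    rp = fit_count_glm(y, X, family="poisson")
    rn = fit_count_glm(y, X, family="negative_binomial")
    # alpha-hat on Poisson data is boundary-consistent, O(n^-1/2) noise
    assert rn.dispersion < 0.05
    assert rn.table["estimate"].to_numpy() == pytest.approx(
        rp.table["estimate"].to_numpy(), abs=1e-4
    )


def test_count_glm_rejects_bad_inputs():
    X = pd.DataFrame({"intercept": [1.0, 1.0], "a": [0.0, 1.0]})
    with pytest.raises(GLMError):
        fit_count_glm(np.array([-1, 2]), X)
    with pytest.raises(GLMError):
        fit_count_glm(np.array([1.5, 2.0]), X)
    Xdup = pd.DataFrame({"intercept": [1.0] * 4, "a": [0, 1, 0, 1], "b": [0, 1, 0, 1]}, dtype=float)
    with pytest.raises(GLMError, match="rank"):
        fit_count_glm(np.array([1, 2, 1, 2]), Xdup)


def test_logistic_reproduces_2x2_cross_product_odds_ratio():
    X = pd.DataFrame({"intercept": 1.0, "exposed": [1.0] * 100 + [0.0] * 100})
    y = np.array([1] * 10 + [0] * 90 + [1] * 5 + [0] * 95)
    r = fit_mortality_glm(y, X)
    assert r.table.set_index("term").loc["exposed", "ratio"] == pytest.approx(
        (10 * 95) / (90 * 5), abs=1e-6
    )


def test_logistic_balanced_null_gives_unit_odds_ratio():
    X = pd.DataFrame({"intercept": 1.0, "exposed": [1.0, 1.0, 0.0, 0.0]})
    y = np.array([1, 0, 1, 0])
    r = fit_mortality_glm(y, X)
    assert r.table.set_index("term").loc["exposed", "ratio"] == pytest.approx(1.0, abs=1e-6)


def test_logistic_requires_both_levels_and_flags_separation():
    X = pd.DataFrame({"intercept": 1.0, "exposed": [1.0] * 5 + [0.0] * 5})
    with pytest.raises(GLMError, match="levels"):
        fit_mortality_glm(np.zeros(10), X)
    y = np.array([1] * 5 + [0] * 5)  # exposure perfectly predicts death
    with pytest.raises(GLMError, match="separation"):
        fit_mortality_glm(y, X)


def test_estimates_invariant_to_row_permutation():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"intercept": 1.0, "g": rng.integers(0, 2, 500).astype(float),
                      "x": rng.normal(size=500)})
    y = rng.poisson(np.exp(0.5 + 0.3 * X["g"] + 0.1 * X["x"]))
    perm = rng.permutation(500)
    r1 = fit_count_glm(y, X, family="poisson")
    r2 = fit_count_glm(y[perm], X.iloc[perm].reset_index(drop=True), family="poisson")
    assert r1.table["estimate"].to_numpy() == pytest.approx(
        r2.table["estimate"].to_numpy(), abs=1e-8
    )
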