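"""Cohort model: multimorbidity definition, stratification, splitting,
descriptive summaries, independence tests, combination counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmclust import (
    CohortTable,
    LCAParameters,
    chisq_independence,
    combination_frequencies,
    default_truth,
    is_multimorbid,
    morbidity_count,
    simulate_cohort,
    split_train_test,
    stratify_by_age,
    summarize_demographics,
)
from mmclust.cohort import CohortValidationError
from mmclust.registry import condition_columns
from mmclust.simulate import SimulationTruth, StratumSpec


def _tiny_cohort(conditions, ages=None, **extra):
    """Build a minimal cohort from a list of condition index-tuples."""
    J = 5
    n = len(conditions)
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age": ages if ages is not None else [50] * n,
            "gender": extra.get("gender", ["F"] * n),
            "imd": extra.get("imd", [3] * n),
            "smoking": extra.get("smoking", ["never"] * n),
            "bmi": extra.get("bmi", [27.0] * n),
            "gp_consults": 0, "hospitalisations": 0, "regular_meds": 0,
            "died_2yr": 0, "died_5yr": 0,
        }
    )
    for j, col in enumerate(condition_columns(J)):
        df[col] = [1 if j in c else 0 for c in conditions]
    return CohortTable(data=df, condition_registry=[f"c{j}" for j in range(J)])


@pytest.mark.parametrize(
    "flags,count,mm",
    [((), 0, False), ((0,), 1, False), ((0, 3), 2, True), ((0, 1, 2, 3, 4), 5, True)],
)
def test_multimorbidity_is_two_or_more_conditions(flags, count, mm):
    c = _tiny_cohort([flags])
    assert morbidity_count(c).iloc[0] == count
    assert bool(is_multimorbid(c).iloc[0]) is mm


def test_age_stratification_boundaries_and_partition():
    ages = [18, 44, 45, 64, 65, 84, 85, 99]
    c = _tiny_cohort([(0, 1)] * len(ages), ages=ages)
    by = stratify_by_age(c)
    assert by["18-44"].data["age"].tolist() == [18, 44]
    assert by["45-64"].data["age"].tolist() == [45, 64]
    assert by["65-84"].data["age"].tolist() == [65, 84]
    assert by["85+"].data["age"].tolist() == [85, 99]
    assert sum(t.n for t in by.values()) == c.n


def test_stratification_rejects_minors():
    c = _tiny_cohort([(0, 1)], ages=[17])
    with pytest.raises(CohortValidationError):
        stratify_by_age(c)


def test_split_respects_per_stratum_floor_sizes_and_is_seeded():
    # strata sizes (153, 361, 495, 123) at fraction 0.8 -> (122, 288, 396, 98)
    sizes = {"18-44": 153, "45-64": 361, "65-84": 495, "85+": 123}
    ages, conds = [], []
    for lab, lo in [("18-44", 20), ("45-64", 50), ("65-84", 70), ("85+", 90)]:
        ages += [lo] * sizes[lab]
        conds += [(0, 1)] * sizes[lab]
    c = _tiny_cohort(conds, ages=ages)
    train, test = split_train_test(c, 0.8, seed=7)
    got = {lab: t.n for lab, t in stratify_by_age(train).items()}
    assert got == {"18-44": 122, "45-64": 288, "65-84": 396, "85+": 98}
    assert train.n + test.n == c.n
    assert not set(train.data["patient_id"]) & set(test.data["patient_id"])
    train2, test2 = split_train_test(c, 0.8, seed=7)
    assert train.data["patient_id"].tolist() == train2.data["patient_id"].tolist()


def test_demographic_summary_quartiles_and_percentages():
    # morbidity counts {2,2,3,4}: median 2.5, Q1 2, Q3 3.25 (linear interp)
    c = _tiny_cohort(
        [(0, 1), (1, 2), (0, 1, 2), (0, 1, 2, 3)],
        imd=[5, 5, 5, 5], gender=["F", "F", "M", "F"],
    )
    s = summarize_demographics(c, "overall").iloc[0]
    assert s["morbidity_median"] == 2.5
    assert s["morbidity_q1"] == 2.0
    assert s["morbidity_q3"] == 3.25
    assert s["pct_greater_deprivation"] == 100.0
    assert s["pct_female"] == 75.0
    assert s["pct_multimorbid"] == 100.0


def test_single_patient_summary_is_degenerate():
    c = _tiny_cohort([(0, 1, 2)])
    s = summarize_demographics(c, "overall").iloc[0]
    assert (s["morbidity_median"], s["morbidity_q1"], s["morbidity_q3"]) == (3, 3, 3)


def test_summary_unknown_grouping_errors():
    with pytest.raises(CohortValidationError):
        summarize_demographics(_tiny_cohort([(0, 1)]), "shoe_size")


def test_chisq_zero_for_proportional_table():
    stat, df, p = chisq_independence([[10, 20], [30, 60]])
    # Yates correction keeps the statistic at its floor of 0 here
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1


def test_chisq_rejects_bad_tables():
    with pytest.raises(CohortValidationError):
        chisq_independence([[1, -2], [3, 4]])
    with pytest.raises(CohortValidationError):
        chisq_independence([[0, 0], [3, 4]])


@given(
    st.lists(
        st.lists(st.integers(min_value=1, max_value=200), min_size=2, max_size=4),
        min_size=2,
        max_size=4,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_chisq_matches_brute_force(rows):
    """Pearson statistic equals the explicit double loop over cells
    (Yates-corrected when the table is 2x2)."""
    t = np.array(rows, dtype=float)
    stat, df, p = chisq_independence(t)
    total = t.sum()
    brute = 0.0
    yates = t.shape == (2, 2)
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = t[i].sum() * t[:, j].sum() / total
            d = abs(t[i, j] - e)
            if yates:
                d = max(d - 0.5, 0.0)
            brute += d * d / e
    assert stat == pytest.approx(brute, rel=1e-12)
    assert df == (t.shape[0] - 1) * (t.shape[1] - 1)


def test_combination_frequencies_counts_and_order():
    c = _tiny_cohort([(0, 1), (0, 1), (0, 2)])
    f = combination_frequencies(c)
    assert f["count"].tolist() == [2, 1]
    assert f["combination"].tolist() == ["c0+c1", "c0+c2"]
    assert f["count"].sum() == c.n


def test_point_mass_classes_yield_exactly_two_combinations():
    rho = np.zeros((2, 6))
    rho[0, :3] = 1.0
    rho[1, 3:] = 1.0
    from conftest import _stratum_outcomes

    spec = StratumSpec(
        label="45-64", n_patients=300, age_range=(45, 64),
        params=LCAParameters(pi=np.array([0.5, 0.5]), rho=rho),
        outcomes=_stratum_outcomes(2)[0],
    )
    cohort, _ = simulate_cohort(SimulationTruth(strata=[spec], seed=3))
    f = combination_frequencies(cohort)
    assert len(f) == 2
    assert f["count"].sum() == 300


def test_descriptives_on_default_study_cohort():
    """The study-like generator produces the expected stratified structure."""
    cohort, _ = simulate_cohort(default_truth(scale=100, seed=0))
    by = stratify_by_age(cohort)
    assert {lab: t.n for lab, t in by.items()} == {
        "18-44": 153, "45-64": 361, "65-84": 495, "85+": 123,
    }
    s = summarize_demographics(cohort, "age_stratum")
    older = s.set_index("group").loc["85+"]
    younger = s.set_index("group").loc["18-44"]
    assert older["morbidity_median"] >= younger["morbidity_median"]
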