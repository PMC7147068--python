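"""Cohort container, multimorbidity definition, age stratification,
train/test splitting, descriptive summaries and independence tests.

A cohort is a patient-level table: demographics (age, gender, IMD quintile,
smoking status, BMI), a fixed panel of binary long-term-condition flags,
and one-year service-use counts plus 2- and 5-year mortality indicators.
A patient is *multimorbid* when two or more condition flags are set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .registry import DEFAULT_CONDITIONS, condition_columns

GENDER_VALUES = ("M", "F")
SMOKING_VALUES = ("current", "never", "ex")


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AgeStratum:
    """Closed-open age interval; ``upper=None`` means unbounded above."""

    label: str
    lower: int
    upper: int | None

    def contains(self, age) -> np.ndarray:
        age = np.asarray(age)
        hi = np.inf if self.upper is None else self.upper
        return (age >= self.lower) & (age < hi)


DEFAULT_AGE_STRATA: tuple[AgeStratum, ...] = (
    AgeStratum("18-44", 18, 45),
    AgeStratum("45-64", 45, 65),
    AgeStratum("65-84", 65, 85),
    AgeStratum("85+", 85, None),
)


@dataclass
class CohortTable:
    """Patient-level table plus the ordered condition-name registry.

    ``data`` columns: patient_id, age, gender {M,F}, imd {1..5}, smoking
    {current,never,ex or NaN}, bmi (kg/m^2, may be NaN), cond_01.. (0/1),
    gp_consults, hospitalisations, regular_meds, died_2yr, died_5yr.
    """

    data: pd.DataFrame
    condition_registry: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))

    def __post_init__(self) -> None:
        names = self.condition_registry
        if len(set(names)) != len(names):
            raise CohortValidationError("condition names must be unique")
        missing = [c for c in self.condition_cols if c not in self.data.columns]
        if missing:
            raise CohortValidationError(f"cohort missing condition columns: {missing}")

    @property
    def condition_cols(self) -> list[str]:
        return condition_columns(len(self.condition_registry))

    @property
    def n(self) -> int:
        return len(self.data)

    def condition_matrix(self) -> np.ndarray:
        return self.data[self.condition_cols].to_numpy(dtype=np.int8)

    def subset(self, mask) -> "CohortTable":
        return replace(self, data=self.data.loc[mask].copy())


def morbidity_count(cohort: CohortTable) -> pd.Series:
    """Number of long-term conditions per patient."""
    return cohort.data[cohort.condition_cols].sum(axis=1)


def is_multimorbid(cohort: CohortTable) -> pd.Series:
    """True when a patient has two or more long-term conditions."""
    return morbidity_count(cohort) >= 2


def filter_multimorbid(cohort: CohortTable) -> CohortTable:
    return cohort.subset(is_multimorbid(cohort).to_numpy())


def stratify_by_age(
    cohort: CohortTable, strata: tuple[AgeStratum, ...] = DEFAULT_AGE_STRATA
) -> dict[str, CohortTable]:
    """Partition the cohort into age strata (every record in exactly one)."""
    age = cohort.data["age"].to_numpy()
    if np.any(age < 18):
        raise CohortValidationError("ages below 18 are outside the study population")
    out: dict[str, CohortTable] = {}
    assigned = np.zeros(len(age), dtype=bool)
    for s in strata:
        m = s.contains(age)
        out[s.label] = cohort.subset(m)
        assigned |= m
    if not assigned.all():
        raise CohortValidationError("age strata do not cover all records")
    return out


def split_train_test(
    cohort: CohortTable,
    train_fraction: float = 0.8,
    seed: int | None = None,
    strata: tuple[AgeStratum, ...] = DEFAULT_AGE_STRATA,
) -> tuple[CohortTable, CohortTable]:
    """Stratified random split: within each age stratum, floor(f * n) patients
    go to the training set; disjoint and exhaustive; reproducible by seed."""
    if not 0 < train_fraction < 1:
        raise CohortValidationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    age = cohort.data["age"].to_numpy()
    train_mask = np.zeros(len(age), dtype=bool)
    for s in strata:
        idx = np.flatnonzero(s.contains(age))
        if idx.size == 0:
            warnings.warn(f"age stratum {s.label} is empty", RuntimeWarning, stacklevel=2)
            continue
        n_train = int(np.floor(train_fraction * idx.size))
        chosen = rng.permutation(idx)[:n_train]
        train_mask[chosen] = True
    return cohort.subset(train_mask), cohort.subset(~train_mask)


def _quartile_str(x: pd.Series) -> tuple[float, float, float]:
    x = x.dropna()
    if x.empty:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return (med, q1, q3)


def summarize_demographics(cohort: CohortTable, grouping: str = "age_stratum") -> pd.DataFrame:
    """Per-group descriptive summary (counts/percentages for categorical
    variables, median [Q1-Q3] for ordinal ones), mirroring standard cohort
    characteristic tables."""
    df = cohort.data
    counts = morbidity_count(cohort)
    if grouping == "age_stratum":
        keys = pd.Series("", index=df.index, dtype=object)
        for s in DEFAULT_AGE_STRATA:
            keys[np.asarray(s.contains(df["age"]))] = s.label
    elif grouping == "overall":
        keys = pd.Series("all", index=df.index)
    elif grouping in df.columns:
        keys = df[grouping].astype(str)
    else:
        raise CohortValidationError(f"unknown grouping field: {grouping!r}")

    rows = []
    total = len(df)
    for g, idx in df.groupby(keys).groups.items():
        sub = df.loc[idx]
        mc = counts.loc[idx]
        med, q1, q3 = _quartile_str(mc)
        bmed, bq1, bq3 = _quartile_str(sub["bmi"])
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "pct_of_total": 100.0 * len(sub) / total,
                "morbidity_median": med,
                "morbidity_q1": q1,
                "morbidity_q3": q3,
                "pct_multimorbid": 100.0 * (mc >= 2).mean(),
                "pct_female": 100.0 * (sub["gender"] == "F").mean(),
                "pct_current_smoker": 100.0 * (sub["smoking"] == "current").mean(),
                "pct_greater_deprivation": 100.0 * sub["imd"].isin([4, 5]).mean(),
                "bmi_median": bmed,
                "bmi_q1": bq1,
                "bmi_q3": bq3,
                "pct_smoking_missing": 100.0 * sub["smoking"].isna().mean(),
                "pct_bmi_missing": 100.0 * sub["bmi"].isna().mean(),
            }
        )
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c contingency
    table of counts; Yates continuity correction applied for 2x2 tables.

    Returns (statistic, degrees of freedom, p-value).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise CohortValidationError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise CohortValidationError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise CohortValidationError("zero row/column margin")
    res = stats.chi2_contingency(t, correction=True)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def combination_frequencies(cohort: CohortTable, min_count: int = 1) -> pd.DataFrame:
    """Exact counts of distinct full condition combinations, sorted by count
    descending with ties broken lexicographically by condition indices."""
    y = cohort.condition_matrix()
    uniq, counts = np.unique(y, axis=0, return_counts=True)
    idx_sets = [tuple(np.flatnonzero(row)) for row in uniq]
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], idx_sets[i]))
    reg = cohort.condition_registry
    rows = [
        {
            "combination": "+".join(reg[j] for j in idx_sets[i]) or "(none)",
            "n_conditions": len(idx_sets[i]),
            "count": int(counts[i]),
            "pct_of_total": 100.0 * counts[i] / max(len(y), 1),
        }
        for i in order
        if counts[i] >= min_count
    ]
    return pd.DataFrame(rows)
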