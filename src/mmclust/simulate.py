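"""Synthetic electronic-health-record cohort generator.

Generates CPRD-like multimorbid cohorts with known latent-class ground
truth so that every downstream stage (stratification, clustering, model
selection, hold-out validation, outcome models) is testable without any
data access.  Conditions arise from the same latent class model the
pipeline fits: a patient draws a class k ~ pi and then each condition
j ~ Bernoulli(rho[k, j]) independently.

Outcomes are generated on the linear-predictor scale: one-year counts
(GP consultations, hospitalisations, regular medications) from a negative
binomial with log link (Poisson when the dispersion is null), 2-year death
from a logistic model, and 5-year death hierarchically — anyone dead at 2
years is dead at 5 years; survivors draw a second Bernoulli — so
``died_2yr => died_5yr`` holds by construction.

``default_truth`` encodes a 4-stratum study design whose stratum sizes,
demographic mixes, class shares, lead/key-condition prevalences and
outcome levels mirror a large English primary-care multimorbidity cohort;
stratum sizes scale down by an integer factor for desk-size runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .lca import LCAParameters
from .registry import DEFAULT_CONDITIONS, condition_columns


class SimulationError(ValueError):
    pass


@dataclass
class OutcomeCoefficients:
    """Linear predictor for one outcome: intercept + per-class effect +
    covariate terms.  Scale is log(mean) for counts and logit(probability)
    for mortality; for 5-year mortality the predictor is the *conditional*
    probability of dying between years 2 and 5 given 2-year survival.
    Age and BMI enter centred at ``age_center`` / ``bmi_center``."""

    intercept: float
    per_class: tuple[float, ...]
    female: float = 0.0
    imd: float = 0.0
    smoking_current: float = 0.0
    smoking_ex: float = 0.0
    age: float = 0.0
    bmi: float = 0.0
    age_center: float = 0.0
    bmi_center: float = 0.0

    def linear_predictor(self, labels: np.ndarray, cov: pd.DataFrame) -> np.ndarray:
        pc = np.asarray(self.per_class, dtype=float)
        lp = self.intercept + pc[labels]
        lp = lp + self.female * cov["female"].to_numpy(dtype=float)
        lp = lp + self.imd * cov["imd"].to_numpy(dtype=float)
        lp = lp + self.smoking_current * cov["smoking_current"].to_numpy(dtype=float)
        lp = lp + self.smoking_ex * cov["smoking_ex"].to_numpy(dtype=float)
        lp = lp + self.age * (cov["age"].to_numpy(dtype=float) - self.age_center)
        lp = lp + self.bmi * (cov["bmi"].to_numpy(dtype=float) - self.bmi_center)
        return lp


COUNT_OUTCOMES = ("gp_consults", "hospitalisations", "regular_meds")
MORTALITY_OUTCOMES = ("died_2yr", "died_5yr")


@dataclass
class StratumSpec:
    """Generating description of one age stratum."""

    label: str
    n_patients: int
    age_range: tuple[int, int]  # inclusive integer years
    params: LCAParameters
    female_prop: float = 0.5
    imd_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    smoking_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)  # current/never/ex
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    smoking_missing_rate: float = 0.0
    bmi_missing_rate: float = 0.0
    outcomes: dict[str, OutcomeCoefficients] = field(default_factory=dict)
    dispersion: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SimulationError("n_patients must be >= 1")
        for name, p in (("imd_probs", self.imd_probs), ("smoking_probs", self.smoking_probs)):
            if abs(sum(p) - 1.0) > 1e-12 or min(p) < 0:
                raise SimulationError(f"{name} must be a probability vector summing to 1")
        for r in (self.smoking_missing_rate, self.bmi_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise SimulationError("missingness rates must lie in [0, 1]")
        for oc in self.outcomes.values():
            if len(oc.per_class) != self.params.K:
                raise SimulationError("per_class effect length must equal K")


@dataclass
class SimulationTruth:
    """Full generating description of a multi-stratum cohort."""

    strata: list[StratumSpec]
    seed: int = 0


def simulate_conditions(
    params: LCAParameters, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an (n x J) binary condition matrix and true class labels from
    the latent class model: class k ~ pi, then condition j ~ Bern(rho[k,j])."""
    if not isinstance(params, LCAParameters):
        params = LCAParameters(*params)
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(params.K, size=n, p=params.pi)
    y = (rng.random((n, params.J)) < params.rho[labels]).astype(np.int8)
    return y, labels


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None or dispersion == 0:
        return rng.poisson(mu)
    # NB2: var = mu + dispersion * mu^2
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_outcomes(
    class_labels: np.ndarray,
    covariates: pd.DataFrame,
    coefficients: Mapping[str, OutcomeCoefficients],
    dispersion: Mapping[str, float | None] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw service-use counts and mortality indicators for each patient.

    ``covariates`` needs columns female, imd, smoking_current, smoking_ex,
    age, bmi aligned row-wise with ``class_labels``.
    """
    labels = np.asarray(class_labels)
    if len(labels) != len(covariates):
        raise SimulationError(
            f"labels ({len(labels)}) and covariates ({len(covariates)}) misaligned"
        )
    dispersion = dict(dispersion or {})
    rng = np.random.default_rng(seed)
    out = pd.DataFrame(index=covariates.index)
    for name in COUNT_OUTCOMES:
        if name not in coefficients:
            raise SimulationError(f"missing coefficients for outcome {name!r}")
        mu = np.exp(coefficients[name].linear_predictor(labels, covariates))
        out[name] = _draw_counts(rng, mu, dispersion.get(name))
    p2 = 1.0 / (1.0 + np.exp(-coefficients["died_2yr"].linear_predictor(labels, covariates)))
    d2 = rng.random(len(labels)) < p2
    # conditional probability of death in years 2-5 given 2-year survival
    q = 1.0 / (1.0 + np.exp(-coefficients["died_5yr"].linear_predictor(labels, covariates)))
    d5 = d2 | (rng.random(len(labels)) < q)
    out["died_2yr"] = d2.astype(int)
    out["died_5yr"] = d5.astype(int)
    return out


def simulate_cohort(truth: SimulationTruth) -> tuple[CohortTable, pd.DataFrame]:
    """Generate the full cohort CSV-shaped table plus a side truth table.

    Returns ``(cohort, truth_table)``; the truth table carries patient_id,
    stratum label and the generating class label, and is never part of the
    cohort itself (a real extract would not contain it).
    """
    ss = np.random.SeedSequence(truth.seed)
    frames: list[pd.DataFrame] = []
    truths: list[pd.DataFrame] = []
    offset = 0
    J = truth.strata[0].params.J if truth.strata else 0
    cond_cols = condition_columns(J)
    for spec, child in zip(truth.strata, ss.spawn(len(truth.strata))):
        seeds = child.generate_state(4) % (2**31)
        n = spec.n_patients
        y, labels = simulate_conditions(spec.params, n, int(seeds[0]))
        rng = np.random.default_rng(int(seeds[1]))
        lo, hi = spec.age_range
        age = rng.integers(lo, hi + 1, size=n)
        female = rng.random(n) < spec.female_prop
        imd = rng.choice([1, 2, 3, 4, 5], size=n, p=spec.imd_probs)
        smoking = rng.choice(np.array(["current", "never", "ex"]), size=n, p=spec.smoking_probs)
        bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n).round(1)
        bmi = np.clip(bmi, 13.0, 70.0)
        cov = pd.DataFrame(
            {
                "age": age,
                "female": female.astype(int),
                "imd": imd,
                "smoking_current": (smoking == "current").astype(int),
                "smoking_ex": (smoking == "ex").astype(int),
                "bmi": bmi,
            }
        )
        outcomes = simulate_outcomes(labels, cov, spec.outcomes, spec.dispersion, int(seeds[2]))
        # inject missingness after outcome generation
        rng_m = np.random.default_rng(int(seeds[3]))
        smoking = smoking.astype(object)
        smoking[rng_m.random(n) < spec.smoking_missing_rate] = np.nan
        bmi = bmi.astype(object)
        bmi[rng_m.random(n) < spec.bmi_missing_rate] = np.nan
        ids = [f"P{offset + i + 1:07d}" for i in range(n)]
        offset += n
        df = pd.DataFrame({"patient_id": ids, "age": age})
        df["gender"] = np.where(female, "F", "M")
        df["imd"] = imd
        df["smoking"] = smoking
        df["bmi"] = pd.to_numeric(bmi, errors="coerce")
        df[cond_cols] = y
        for c in outcomes.columns:
            df[c] = outcomes[c].to_numpy()
        frames.append(df)
        truths.append(
            pd.DataFrame({"patient_id": ids, "stratum": spec.label, "true_class": labels})
        )
    data = pd.concat(frames, ignore_index=True)
    registry = list(DEFAULT_CONDITIONS[:J]) if J <= len(DEFAULT_CONDITIONS) else [
        f"condition_{j+1}" for j in range(J)
    ]
    return CohortTable(data=data, condition_registry=registry), pd.concat(
        truths, ignore_index=True
    )


# ---------------------------------------------------------------------------
# Built-in fixtures: contingency tables reconstructed from the published
# whole-population counts (N = 391,669; multimorbid N = 113,211).
# ---------------------------------------------------------------------------

TOTAL_PATIENTS = 391_669
TOTAL_MULTIMORBID = 113_211
_MALE_TOTAL, _FEMALE_TOTAL = 192_929, 198_740
_FEMALE_MULTIMORBID = 63_072
_IMD_TOTALS = (90_730, 87_734, 81_569, 71_424, 60_212)
_IMD_MULTIMORBID = (24_624, 25_027, 23_700, 20_934, 18_926)


def gender_multimorbidity_table() -> pd.DataFrame:
    """2x2 gender-by-multimorbidity contingency table (counts)."""
    male_mm = TOTAL_MULTIMORBID - _FEMALE_MULTIMORBID
    return pd.DataFrame(
        {
            "multimorbid": [male_mm, _FEMALE_MULTIMORBID],
            "not_multimorbid": [_MALE_TOTAL - male_mm, _FEMALE_TOTAL - _FEMALE_MULTIMORBID],
        },
        index=pd.Index(["M", "F"], name="gender"),
    )


def imd_multimorbidity_table() -> pd.DataFrame:
    """5x2 IMD-quintile-by-multimorbidity contingency table (counts)."""
    return pd.DataFrame(
        {
            "multimorbid": list(_IMD_MULTIMORBID),
            "not_multimorbid": [t - m for t, m in zip(_IMD_TOTALS, _IMD_MULTIMORBID)],
        },
        index=pd.Index([1, 2, 3, 4, 5], name="imd"),
    )


def builtin_fixtures() -> dict:
    """Named small datasets reconstructed from published counts."""
    return {
        "gender_multimorbidity": gender_multimorbidity_table(),
        "imd_multimorbidity": imd_multimorbidity_table(),
        "total_patients": TOTAL_PATIENTS,
        "total_multimorbid": TOTAL_MULTIMORBID,
    }


# ---------------------------------------------------------------------------
# Default study-condition truth
# ---------------------------------------------------------------------------

_C = {name: i for i, name in enumerate(DEFAULT_CONDITIONS)}

# (share, {condition: within-class prevalence}) per stratum; shares are the
# published cluster sizes, profiles the published lead/key-condition
# prevalences.  Conditions not listed sit at the stratum background level.
_STRATUM_CLUSTERS: dict[str, list[tuple[float, dict[str, float]]]] = {
    "18-44": [
        (0.32, {"depression": 1.00, "anxiety": 0.41, "painful_condition": 0.31}),
        (0.23, {"painful_condition": 0.36, "hearing_loss": 0.30, "hypertension": 0.23}),
        (0.20, {"asthma": 1.00, "irritable_bowel_syndrome": 0.26, "depression": 0.20}),
        (0.18, {"irritable_bowel_syndrome": 1.00, "depression": 0.29, "hearing_loss": 0.21}),
        (0.07, {"psychoactive_substance_misuse": 0.75, "alcohol_problems": 0.42, "depression": 0.24}),
    ],
    "45-64": [
        (0.37, {"hypertension": 0.76, "diabetes": 0.37, "painful_condition": 0.25}),
        (0.24, {"irritable_bowel_syndrome": 0.40, "hearing_loss": 0.29, "painful_condition": 0.28}),
        (0.22, {"depression": 0.93, "painful_condition": 0.53, "anxiety": 0.31}),
        (0.12, {"asthma": 1.00, "painful_condition": 0.24, "copd": 0.16}),
        (0.04, {"alcohol_problems": 0.62, "psychoactive_substance_misuse": 0.42, "painful_condition": 0.28}),
    ],
    "65-84": [
        (0.41, {"hypertension": 1.00, "diabetes": 0.31, "painful_condition": 0.27}),
        (0.22, {"hearing_loss": 0.40, "prostate_disorders": 0.21, "irritable_bowel_syndrome": 0.03}),
        (0.14, {"depression": 0.56, "painful_condition": 0.56, "anxiety": 0.23}),
        (0.11, {"coronary_heart_disease": 0.54, "diabetes": 0.32, "atrial_fibrillation": 0.29}),
        (0.08, {"copd": 0.57, "asthma": 0.49, "painful_condition": 0.33}),
        (0.05, {"painful_condition": 0.81, "coronary_heart_disease": 0.53, "depression": 0.45}),
    ],
    "85+": [
        (0.58, {"hypertension": 0.72, "hearing_loss": 0.39, "diabetes": 0.18}),
        (0.23, {"painful_condition": 0.64, "depression": 0.41, "constipation": 0.24}),
        (0.11, {"coronary_heart_disease": 0.61, "atrial_fibrillation": 0.53, "heart_failure": 0.49}),
        (0.08, {"asthma": 0.48, "copd": 0.48, "painful_condition": 0.44}),
    ],
}

_STRATUM_SIZES = {"18-44": 15_306, "45-64": 36_097, "65-84": 49_494, "85+": 12_314}
_AGE_RANGES = {"18-44": (18, 44), "45-64": (45, 64), "65-84": (65, 84), "85+": (85, 99)}
_BACKGROUND = {"18-44": 0.04, "45-64": 0.05, "65-84": 0.07, "85+": 0.10}
_FEMALE = {"18-44": 0.62, "45-64": 0.55, "65-84": 0.52, "85+": 0.65}
_IMD_PROBS = {
    "18-44": (0.17, 0.18, 0.19, 0.22, 0.24),
    "45-64": (0.20, 0.21, 0.20, 0.19, 0.20),
    "65-84": (0.24, 0.24, 0.21, 0.17, 0.14),
    "85+": (0.24, 0.24, 0.22, 0.17, 0.13),
}
_SMOKING_PROBS = {
    "18-44": (0.37, 0.45, 0.18),
    "45-64": (0.25, 0.47, 0.28),
    "65-84": (0.12, 0.49, 0.39),
    "85+": (0.05, 0.60, 0.35),
}
_BMI = {"18-44": (26.5, 5.5), "45-64": (28.5, 5.5), "65-84": (27.5, 5.0), "85+": (25.0, 4.5)}
_MISSING = {  # (smoking, bmi) missingness rates
    "18-44": (0.0036, 0.10),
    "45-64": (0.0013, 0.04),
    "65-84": (0.0008, 0.03),
    "85+": (0.0058, 0.10),
}
# per-cluster published outcome levels, ordered as _STRATUM_CLUSTERS:
# (mean GP contacts, mean hospitalisations, mean regular meds, 2-yr %, 5-yr %)
_OUTCOME_LEVELS = {
    "18-44": [
        (14.5, 0.4, 2.4, 0.9, 1.8),
        (11.9, 0.6, 2.5, 1.0, 2.7),
        (11.3, 0.4, 1.9, 0.2, 0.6),
        (10.6, 0.4, 1.2, 0.2, 0.4),
        (10.7, 0.4, 1.3, 1.8, 3.9),
    ],
    "45-64": [
        (11.5, 0.5, 4.1, 1.6, 4.4),
        (10.5, 0.5, 2.0, 1.3, 3.0),
        (16.7, 0.6, 5.1, 2.4, 5.8),
        (12.6, 0.4, 3.4, 1.0, 2.7),
        (10.7, 0.5, 2.4, 4.5, 12.5),
    ],
    "65-84": [
        (12.4, 0.6, 4.5, 4.7, 13.2),
        (13.2, 0.7, 3.3, 4.4, 11.1),
        (17.3, 0.8, 5.9, 8.4, 20.9),
        (16.8, 1.1, 5.9, 11.3, 28.8),
        (15.7, 0.8, 5.5, 9.2, 25.5),
        (26.3, 1.6, 10.7, 16.2, 39.2),
    ],
    "85+": [
        (13.0, 0.8, 4.1, 20.9, 49.5),
        (17.3, 0.8, 6.7, 31.1, 62.9),
        (21.9, 1.5, 8.0, 37.7, 70.8),
        (19.6, 1.1, 6.9, 28.0, 56.5),
    ],
}
_DISPERSION = {"gp_consults": 0.35, "hospitalisations": 1.0, "regular_meds": 0.6}


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _stratum_params(label: str) -> LCAParameters:
    clusters = _STRATUM_CLUSTERS[label]
    shares = np.array([s for s, _ in clusters], dtype=float)
    pi = shares / shares.sum()
    bg = _BACKGROUND[label]
    rho = np.full((len(clusters), len(DEFAULT_CONDITIONS)), bg)
    for k, (_, profile) in enumerate(clusters):
        for cond, prev in profile.items():
            rho[k, _C[cond]] = prev
    return LCAParameters(pi=pi, rho=rho)


def _stratum_outcomes(label: str, K: int) -> tuple[dict, dict]:
    levels = _OUTCOME_LEVELS[label]
    coeffs: dict[str, OutcomeCoefficients] = {}
    for i, name in enumerate(COUNT_OUTCOMES):
        base = max(levels[0][i], 0.05)
        per_class = tuple(float(np.log(max(l[i], 0.05) / base)) for l in levels)
        coeffs[name] = OutcomeCoefficients(intercept=float(np.log(base)), per_class=per_class)
    p2 = [l[3] / 100.0 for l in levels]
    coeffs["died_2yr"] = OutcomeCoefficients(
        intercept=_logit(p2[0]),
        per_class=tuple(_logit(p) - _logit(p2[0]) for p in p2),
    )
    # conditional probability of dying in years 2-5 given 2-year survival
    q = [max((l[4] / 100.0 - a) / (1.0 - a), 1e-6) for l, a in zip(levels, p2)]
    coeffs["died_5yr"] = OutcomeCoefficients(
        intercept=_logit(q[0]),
        per_class=tuple(_logit(x) - _logit(q[0]) for x in q),
    )
    return coeffs, dict(_DISPERSION)


def default_truth(scale: int = 100, seed: int = 0) -> SimulationTruth:
    """The study-condition generating truth: four age strata whose sizes,
    class structure, demographics and outcome levels mirror the published
    multimorbid cohort; ``scale`` divides the stratum sizes (100 -> a
    ~1,100-patient cohort; 10 -> ~11,300)."""
    strata = []
    for label in ("18-44", "45-64", "65-84", "85+"):
        params = _stratum_params(label)
        coeffs, disp = _stratum_outcomes(label, params.K)
        sm_miss, bmi_miss = _MISSING[label]
        strata.append(
            StratumSpec(
                label=label,
                n_patients=max(int(round(_STRATUM_SIZES[label] / scale)), 1),
                age_range=_AGE_RANGES[label],
                params=params,
                female_prop=_FEMALE[label],
                imd_probs=_IMD_PROBS[label],
                smoking_probs=_SMOKING_PROBS[label],
                bmi_mean=_BMI[label][0],
                bmi_sd=_BMI[label][1],
                smoking_missing_rate=sm_miss,
                bmi_missing_rate=bmi_miss,
                outcomes=coeffs,
                dispersion=disp,
            )
        )
    return SimulationTruth(strata=strata, seed=seed)
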