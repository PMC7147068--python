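"""Outcome models: adjusted incidence rate ratios and odds ratios.

Service-use counts (GP consultations, hospitalisations, regular
medications per year) are modelled with log-link count GLMs — negative
binomial by default, with the dispersion found by outer maximisation of
the profile likelihood, or Poisson — and 2-/5-year mortality with
logistic GLMs.  Cluster membership enters as indicators against a
reference cluster (by default the cluster with the lowest impact across
the four outcomes); adjusted covariates are gender, deprivation (IMD),
smoking status, BMI and age.  Records missing smoking or BMI are excluded
first (complete-case analysis), with a warning when the exclusion reaches
5% of the cohort.

Fitting is delegated to statsmodels GLM (iteratively reweighted least
squares); this module owns the design construction, the reference-cluster
rule, the dispersion profile and the reporting conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import rankdata

from .cohort import CohortTable


class GLMError(ValueError):
    pass


def complete_case_filter(cohort: CohortTable) -> tuple[CohortTable, dict]:
    """Drop records missing smoking status or BMI (complete-case analysis).

    Returns the filtered cohort and an exclusion report; warns when the
    excluded share reaches 5%, the level above which complete-case
    analysis becomes questionable.
    """
    df = cohort.data
    missing = df["smoking"].isna() | df["bmi"].isna()
    n_excl = int(missing.sum())
    pct = 100.0 * n_excl / max(len(df), 1)
    report = {"n_total": len(df), "n_excluded": n_excl, "pct_excluded": pct}
    if pct >= 5.0:
        warnings.warn(
            f"complete-case filter excludes {pct:.1f}% of records (>= 5%)",
            RuntimeWarning,
            stacklevel=2,
        )
        report["warning"] = "exclusion >= 5%"
    return cohort.subset(~missing.to_numpy()), report


def choose_reference_cluster(outcome_summary: pd.DataFrame) -> int:
    """The cluster with the lowest impact on the outcomes.

    Default rule: smallest rank-sum across mean GP contacts, mean
    hospitalisations, mean regular medications and 5-year mortality;
    rank-sum ties go to the larger cluster.
    """
    df = outcome_summary[outcome_summary["cluster_id"] != "non_multimorbid"]
    if len(df) < 2:
        raise GLMError("need at least two clusters to choose a reference")
    cols = ["gp_consults_mean", "hospitalisations_mean", "regular_meds_mean", "mortality_5yr_pct"]
    ranks = np.zeros(len(df))
    for c in cols:
        ranks += rankdata(df[c].to_numpy())
    order = sorted(
        range(len(df)),
        key=lambda i: (ranks[i], -df["n"].iloc[i], df["cluster_id"].iloc[i]),
    )
    return int(df["cluster_id"].iloc[order[0]])


def build_design(
    cohort: CohortTable,
    assignments: np.ndarray,
    reference_cluster: int,
    imd_coding: str = "ordinal",
) -> pd.DataFrame:
    """Design matrix for the outcome GLMs.

    Columns (fixed order): intercept; cluster_<k> indicators for every
    cluster except the reference; gender_M (reference female); smoking
    indicators smoking_current and smoking_ex (reference never-smoker);
    imd as a single ordinal 1-5 term (or imd_2..imd_5 indicators when
    ``imd_coding="indicator"``); bmi and age continuous.
    """
    df = cohort.data
    a = np.asarray(assignments)
    if len(a) != len(df):
        raise GLMError("assignments and cohort misaligned")
    if df["smoking"].isna().any() or df["bmi"].isna().any():
        raise GLMError("design requires complete cases; run complete_case_filter first")
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    clusters = sorted(set(a.tolist()))
    if reference_cluster not in clusters:
        raise GLMError(f"reference cluster {reference_cluster} not among assignments")
    for k in clusters:
        if k == reference_cluster:
            continue
        ind = (a == k).astype(float)
        if ind.sum() < 2:
            warnings.warn(f"cluster {k} has < 2 members; dropped from design",
                          RuntimeWarning, stacklevel=2)
            continue
        X[f"cluster_{k}"] = ind
    X["gender_M"] = (df["gender"] == "M").astype(float)
    X["smoking_current"] = (df["smoking"] == "current").astype(float)
    X["smoking_ex"] = (df["smoking"] == "ex").astype(float)
    if imd_coding == "ordinal":
        X["imd"] = df["imd"].astype(float)
    elif imd_coding == "indicator":
        for q in (2, 3, 4, 5):
            X[f"imd_{q}"] = (df["imd"] == q).astype(float)
    else:
        raise GLMError(f"unknown imd_coding {imd_coding!r}")
    X["bmi"] = df["bmi"].astype(float)
    X["age"] = df["age"].astype(float)
    return X


@dataclass
class OutcomeModelResult:
    """One fitted outcome model, reported on the ratio scale."""

    outcome: str
    family: str  # poisson | negative_binomial | logistic
    reference_cluster: int | str | None
    table: pd.DataFrame  # term, estimate, se, ci_low, ci_high, ratio, ratio_ci_*
    n_used: int
    n_excluded_missing: int = 0
    dispersion: float | None = None
    converged: bool = True
    loglik: float | None = None

    @property
    def ratio_label(self) -> str:
        return "OR" if self.family == "logistic" else "aIRR"


def _wald_table(params: pd.Series, bse: pd.Series) -> pd.DataFrame:
    z = 1.959963984540054  # Phi^{-1}(0.975)
    est = params.to_numpy()
    se = bse.to_numpy()
    lo, hi = est - z * se, est + z * se
    return pd.DataFrame(
        {
            "term": params.index,
            "estimate": est,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "ratio": np.exp(est),
            "ratio_ci_low": np.exp(lo),
            "ratio_ci_high": np.exp(hi),
        }
    ).reset_index(drop=True)


_GLM_KW = dict(maxiter=100, tol=1e-8)


def fit_count_glm(
    response,
    design: pd.DataFrame,
    family: str = "negative_binomial",
    reference_cluster=None,
    outcome: str = "count",
) -> OutcomeModelResult:
    """Log-link count GLM; exponentiated coefficients are adjusted
    incidence rate ratios with Wald 95% intervals.

    The negative binomial dispersion alpha (var = mu + alpha mu^2) is
    estimated by maximising the profile log-likelihood over log(alpha)
    with an inner IRLS fit at each candidate."""
    y = np.asarray(response, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise GLMError("count response must be non-negative integers")
    X = design
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise GLMError("design matrix is rank deficient")

    if family == "poisson":
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(**_GLM_KW)
        disp = None
    elif family == "negative_binomial":

        def negll(log_alpha: float) -> float:
            fam = sm.families.NegativeBinomial(alpha=float(np.exp(log_alpha)))
            r = sm.GLM(y, X, family=fam).fit(**_GLM_KW)
            return -r.llf

        opt = minimize_scalar(negll, bounds=(np.log(1e-6), np.log(50.0)),
                              method="bounded", options={"xatol": 1e-4})
        disp = float(np.exp(opt.x))
        res = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=disp)).fit(**_GLM_KW)
    else:
        raise GLMError(f"unknown count family {family!r}")

    if not res.converged:
        raise GLMError(f"count GLM for {outcome!r} did not converge in 100 iterations")
    return OutcomeModelResult(
        outcome=outcome,
        family=family,
        reference_cluster=reference_cluster,
        table=_wald_table(res.params, res.bse),
        n_used=len(y),
        dispersion=disp,
        converged=bool(res.converged),
        loglik=float(res.llf),
    )


def fit_mortality_glm(
    response,
    design: pd.DataFrame,
    reference_cluster=None,
    outcome: str = "mortality",
) -> OutcomeModelResult:
    """Logistic GLM for a binary death indicator; exponentiated
    coefficients are odds ratios with Wald 95% intervals."""
    y = np.asarray(response, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise GLMError("mortality response must be binary 0/1")
    if y.min() == y.max():
        raise GLMError("both outcome levels must be present")
    X = design
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(**_GLM_KW)
    separation_warned = any(
        "separation" in str(w.message).lower() for w in caught
    )
    mu = res.fittedvalues
    if separation_warned or np.any((mu < 1e-10) | (mu > 1 - 1e-10)):
        sep_cols = [
            c for c in X.columns
            if c != "intercept" and X[c].nunique() <= 2 and
            (pd.crosstab(X[c], y).to_numpy() == 0).any()
        ]
        raise GLMError(
            "complete or quasi-separation detected"
            + (f" (suspect columns: {sep_cols})" if sep_cols else "")
        )
    if not res.converged:
        raise GLMError(f"logistic GLM for {outcome!r} did not converge")
    return OutcomeModelResult(
        outcome=outcome,
        family="logistic",
        reference_cluster=reference_cluster,
        table=_wald_table(res.params, res.bse),
        n_used=len(y),
        converged=True,
        loglik=float(res.llf),
    )


def fit_outcome_models(
    cohort: CohortTable,
    assignments: np.ndarray,
    reference_cluster: int,
    family: str = "negative_binomial",
    imd_coding: str = "ordinal",
) -> dict[str, OutcomeModelResult]:
    """Fit all five outcome models on complete cases with a shared design."""
    filtered, report = complete_case_filter(cohort)
    keep = ~(cohort.data["smoking"].isna() | cohort.data["bmi"].isna()).to_numpy()
    a = np.asarray(assignments)[keep]
    X = build_design(filtered, a, reference_cluster, imd_coding=imd_coding)
    out: dict[str, OutcomeModelResult] = {}
    for name in ("gp_consults", "hospitalisations", "regular_meds"):
        r = fit_count_glm(filtered.data[name], X, family=family,
                          reference_cluster=reference_cluster, outcome=name)
        r.n_excluded_missing = report["n_excluded"]
        out[name] = r
    for name in ("died_2yr", "died_5yr"):
        try:
            r = fit_mortality_glm(filtered.data[name], X,
                                  reference_cluster=reference_cluster, outcome=name)
            r.n_excluded_missing = report["n_excluded"]
            out[name] = r
        except GLMError as e:
            warnings.warn(f"{name}: {e}", RuntimeWarning, stacklevel=2)
    return out
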