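"""Cluster profiling: prevalence profiles, distinctiveness, lead/key
condition labels, and per-cluster demographic/outcome summaries.

A cluster's *distinctiveness* for a condition is the difference between
its within-cluster prevalence and the prevalence in the whole age stratum;
clusters are labelled by their lead condition (most distinctive) and their
top three *key conditions*.  Because the lead could plausibly also be
ranked by raw within-cluster prevalence, both orderings are reported when
they differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, morbidity_count


@dataclass
class ClusterProfile:
    cluster_id: int
    stratum: str
    size: int
    pct_of_stratum: float
    within_prevalence: np.ndarray  # (J,)
    strata_prevalence: np.ndarray  # (J,)
    lead_condition: str | None
    lead_prevalence: float
    key_conditions: list[tuple[str, float]]  # (name, within-prevalence)
    lead_by_prevalence: str | None = None  # alternative lead ranked by raw prevalence
    summaries: dict = field(default_factory=dict)

    @property
    def distinctiveness(self) -> np.ndarray:
        return self.within_prevalence - self.strata_prevalence

    def label(self) -> str:
        if not self.key_conditions:
            return "(no distinctive conditions)"
        parts = [f"{n} ({100 * p:.0f}%)" for n, p in self.key_conditions]
        return parts[0] + (" | " + ", ".join(parts[1:]) if len(parts) > 1 else "")


def prevalence_profile(
    assignments: np.ndarray, data: np.ndarray
) -> tuple[dict[int, np.ndarray], np.ndarray, dict[int, int]]:
    """Within-cluster and overall condition prevalences.

    Returns (within: cluster -> (J,) prevalence vector, overall (J,),
    sizes: cluster -> count).  Empty clusters are dropped with a warning.
    """
    a = np.asarray(assignments)
    y = np.asarray(data, dtype=float)
    if len(a) != len(y):
        raise ValueError("assignments and data rows misaligned")
    overall = y.mean(axis=0)
    within: dict[int, np.ndarray] = {}
    sizes: dict[int, int] = {}
    for k in range(int(a.max()) + 1 if a.size else 0):
        mask = a == k
        if not mask.any():
            warnings.warn(f"cluster {k} is empty; dropped", RuntimeWarning, stacklevel=2)
            continue
        within[k] = y[mask].mean(axis=0)
        sizes[k] = int(mask.sum())
    return within, overall, sizes


def key_conditions(
    within: np.ndarray,
    strata: np.ndarray,
    registry: list[str],
    m: int = 3,
) -> list[tuple[str, float]]:
    """Top-m conditions by distinctiveness (within minus stratum prevalence),
    keeping only positive distinctiveness; ties broken by higher
    within-prevalence, then registry order."""
    d = np.asarray(within) - np.asarray(strata)
    order = sorted(range(len(d)), key=lambda j: (-d[j], -within[j], j))
    out = [(registry[j], float(within[j])) for j in order[:m] if d[j] > 0]
    if not out:
        warnings.warn("no condition with positive distinctiveness", RuntimeWarning, stacklevel=2)
    return out


def build_profiles(
    assignments: np.ndarray,
    cohort: CohortTable,
    stratum_label: str = "",
    m: int = 3,
) -> list[ClusterProfile]:
    """Full cluster profiles for one age stratum, ordered by size descending."""
    y = cohort.condition_matrix()
    within, overall, sizes = prevalence_profile(assignments, y)
    reg = cohort.condition_registry
    df = cohort.data
    counts = morbidity_count(cohort)
    profiles = []
    for k, w in within.items():
        keys = key_conditions(w, overall, reg, m=m)
        mask = np.asarray(assignments) == k
        sub = df.loc[mask]
        mc = counts.loc[mask]
        q1, med, q3 = np.quantile(mc, [0.25, 0.5, 0.75]) if len(mc) else (np.nan,) * 3
        summaries = {
            "morbidity_median": float(med),
            "morbidity_q1": float(q1),
            "morbidity_q3": float(q3),
            "pct_female": 100.0 * (sub["gender"] == "F").mean(),
            "pct_greater_deprivation": 100.0 * sub["imd"].isin([4, 5]).mean(),
            "pct_current_smoker": 100.0 * (sub["smoking"] == "current").mean(),
        }
        # alternative lead ranked by raw within-cluster prevalence (must still
        # exceed the stratum prevalence)
        raw_order = sorted(
            range(len(w)), key=lambda j: (-w[j], j)
        )
        lead_raw = next((reg[j] for j in raw_order if w[j] > overall[j]), None)
        profiles.append(
            ClusterProfile(
                cluster_id=k,
                stratum=stratum_label,
                size=sizes[k],
                pct_of_stratum=100.0 * sizes[k] / len(y),
                within_prevalence=w,
                strata_prevalence=overall,
                lead_condition=keys[0][0] if keys else None,
                lead_prevalence=keys[0][1] if keys else np.nan,
                key_conditions=keys,
                lead_by_prevalence=lead_raw,
                summaries=summaries,
            )
        )
    profiles.sort(key=lambda p: (-p.size, p.cluster_id))
    return profiles


def profiles_to_frame(profiles: list[ClusterProfile], registry: list[str]) -> pd.DataFrame:
    """Long-format table: one row per cluster x condition."""
    rows = []
    for p in profiles:
        for j, name in enumerate(registry):
            rows.append(
                {
                    "stratum": p.stratum,
                    "cluster_id": p.cluster_id,
                    "condition": name,
                    "within_prevalence": p.within_prevalence[j],
                    "strata_prevalence": p.strata_prevalence[j],
                    "distinctiveness": p.within_prevalence[j] - p.strata_prevalence[j],
                }
            )
    return pd.DataFrame(rows)


def label_table(profiles: list[ClusterProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "stratum": p.stratum,
                "cluster_id": p.cluster_id,
                "size": p.size,
                "pct_of_stratum": round(p.pct_of_stratum, 1),
                "label": p.label(),
                "lead_condition": p.lead_condition,
                "lead_by_prevalence": p.lead_by_prevalence,
                **{k: round(v, 2) for k, v in p.summaries.items()},
            }
        )
    return pd.DataFrame(rows)


def cluster_outcome_summary(
    assignments: np.ndarray,
    cohort: CohortTable,
    non_multimorbid: CohortTable | None = None,
) -> pd.DataFrame:
    """Per-cluster mortality and service-use summary.

    Rows: one per cluster (ordered by 5-year mortality descending), plus an
    optional non-multimorbid comparison row appended last.  Counts are
    summarised by both mean and median [Q1-Q3] since their distributions
    are right-skewed.
    """
    a = np.asarray(assignments)
    rows = []

    def summarise(sub: pd.DataFrame, cluster) -> dict:
        row = {"cluster_id": cluster, "n": len(sub)}
        row["mortality_2yr_pct"] = 100.0 * sub["died_2yr"].mean()
        row["mortality_5yr_pct"] = 100.0 * sub["died_5yr"].mean()
        for col in ("gp_consults", "hospitalisations", "regular_meds"):
            x = sub[col]
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            row[f"{col}_mean"] = float(x.mean())
            row[f"{col}_median"] = float(med)
            row[f"{col}_q1"] = float(q1)
            row[f"{col}_q3"] = float(q3)
        return row

    for k in sorted(set(a.tolist())):
        rows.append(summarise(cohort.data.loc[a == k], k))
    rows.sort(key=lambda r: -r["mortality_5yr_pct"])
    if non_multimorbid is not None and non_multimorbid.n > 0:
        rows.append(summarise(non_multimorbid.data, "non_multimorbid"))
    return pd.DataFrame(rows).reset_index(drop=True)


def report_markdown(
    profiles_by_stratum: dict[str, list[ClusterProfile]],
    outcomes_by_stratum: dict[str, pd.DataFrame] | None = None,
) -> str:
    """Human-readable cluster report (labels, sizes, summaries, outcomes)."""
    lines = ["# Multimorbidity cluster report", ""]
    for stratum, profiles in profiles_by_stratum.items():
        lines.append(f"## Age {stratum} years")
        lines.append("")
        lines.append("| Cluster | Label | Patients (%) | Morbidities (median [Q1-Q3]) | Female % | Greater deprivation % | Current smokers % |")
        lines.append("|---|---|---|---|---|---|---|")
        for p in profiles:
            s = p.summaries
            lines.append(
                f"| {p.cluster_id} | {p.label()} | {p.size} ({p.pct_of_stratum:.0f}%) | "
                f"{s['morbidity_median']:.0f} [{s['morbidity_q1']:.0f}-{s['morbidity_q3']:.0f}] | "
                f"{s['pct_female']:.0f} | {s['pct_greater_deprivation']:.0f} | {s['pct_current_smoker']:.0f} |"
            )
        lines.append("")
        if outcomes_by_stratum and stratum in outcomes_by_stratum:
            out = outcomes_by_stratum[stratum]
            lines.append("| Cluster | 2-yr mortality % | 5-yr mortality % | GP contacts (mean, median) | Hospitalisations (mean, median) | Regular meds (mean, median) |")
            lines.append("|---|---|---|---|---|---|")
            for _, r in out.iterrows():
                lines.append(
                    f"| {r['cluster_id']} | {r['mortality_2yr_pct']:.1f} | {r['mortality_5yr_pct']:.1f} | "
                    f"{r['gp_consults_mean']:.1f}, {r['gp_consults_median']:.0f} | "
                    f"{r['hospitalisations_mean']:.1f}, {r['hospitalisations_median']:.0f} | "
                    f"{r['regular_meds_mean']:.1f}, {r['regular_meds_median']:.0f} |"
                )
            lines.append("")
    return "\n".join(lines)
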