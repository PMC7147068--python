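"""Reading and writing the cohort CSV and model/result files.

Cohort CSV schema: patient_id, age, gender {M,F}, imd {1..5}, smoking
{current,never,ex, empty = missing}, bmi (kg/m^2, empty = missing),
cond_01..cond_NN (0/1), gp_consults, hospitalisations, regular_meds,
died_2yr, died_5yr (0/1).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .cohort import CohortTable, CohortValidationError
from .lca import LCAFit, LCAParameters
from .registry import DEFAULT_CONDITIONS

log = logging.getLogger("mmclust")

REQUIRED_COLUMNS = [
    "patient_id", "age", "gender", "imd", "smoking", "bmi",
    "gp_consults", "hospitalisations", "regular_meds", "died_2yr", "died_5yr",
]


class SchemaError(ValueError):
    pass


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.data.to_csv(path, index=False)


def read_cohort(path, condition_registry: list[str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    The number of ``cond_NN`` columns determines the registry length; when
    no registry is given, default condition names are used.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    cond_cols = sorted([c for c in df.columns if c.startswith("cond_")])
    if condition_registry is None:
        if len(cond_cols) <= len(DEFAULT_CONDITIONS):
            condition_registry = list(DEFAULT_CONDITIONS[: len(cond_cols)])
        else:
            condition_registry = [f"condition_{i+1}" for i in range(len(cond_cols))]
    expected_cond = [f"cond_{j+1:02d}" for j in range(len(condition_registry))]
    missing = [c for c in REQUIRED_COLUMNS + expected_cond if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required columns: {missing}")

    for c in expected_cond:
        vals = df[c]
        bad = ~vals.isin([0, 1])
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise CohortValidationError(
                f"non-binary values in {c} at rows {rows}"
            )
    bad_gender = ~df["gender"].isin(["M", "F"])
    if bad_gender.any():
        raise CohortValidationError(
            f"invalid gender values at rows {df.index[bad_gender].tolist()[:10]}"
        )
    bad_smoking = df["smoking"].notna() & ~df["smoking"].isin(["current", "never", "ex"])
    if bad_smoking.any():
        raise CohortValidationError(
            f"invalid smoking values {sorted(df.loc[bad_smoking, 'smoking'].unique())} "
            f"at rows {df.index[bad_smoking].tolist()[:10]}"
        )
    bad_imd = ~df["imd"].isin([1, 2, 3, 4, 5])
    if bad_imd.any():
        raise CohortValidationError(
            f"invalid IMD quintiles at rows {df.index[bad_imd].tolist()[:10]}"
        )
    if (df["age"] < 18).any():
        raise CohortValidationError("ages below 18 present")
    df["bmi"] = pd.to_numeric(df["bmi"], errors="raise")
    cohort = CohortTable(data=df, condition_registry=condition_registry)
    log.info("read cohort: %d records, %d conditions", len(df), len(condition_registry))
    return cohort


def save_fit(fit: LCAFit, path, condition_registry=None, extra: dict | None = None) -> None:
    fit.save_json(path, condition_registry=condition_registry, extra=extra)


def load_fit_params(path) -> tuple[LCAParameters, dict]:
    """Load model parameters (not posteriors) from a model JSON."""
    with open(path) as fh:
        d = json.load(fh)
    return LCAParameters(pi=np.array(d["pi"]), rho=np.array(d["rho"])), d


def save_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
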