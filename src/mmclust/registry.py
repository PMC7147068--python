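"""Default long-term-condition registry.

The clustering operates on binary present/absent flags for a fixed panel of
38 chronic conditions, the taxonomy commonly used in UK primary-care
multimorbidity research. Cohort CSV columns are positional (``cond_01`` ..
``cond_38``); this registry supplies the human-readable names aligned to
those columns.
"""

from __future__ import annotations

DEFAULT_CONDITIONS: list[str] = [
    "hypertension",
    "depression",
    "painful_condition",
    "asthma",
    "hearing_loss",
    "irritable_bowel_syndrome",
    "diabetes",
    "coronary_heart_disease",
    "chronic_kidney_disease",
    "atrial_fibrillation",
    "stroke_tia",
    "heart_failure",
    "copd",
    "anxiety",
    "constipation",
    "prostate_disorders",
    "cancer",
    "peripheral_vascular_disease",
    "epilepsy",
    "psoriasis_eczema",
    "thyroid_disorders",
    "rheumatoid_arthritis",
    "alcohol_problems",
    "psychoactive_substance_misuse",
    "psychosis_bipolar",
    "dementia",
    "learning_disability",
    "anorexia_bulimia",
    "migraine",
    "dyspepsia",
    "blindness_low_vision",
    "glaucoma",
    "inflammatory_bowel_disease",
    "diverticular_disease",
    "chronic_sinusitis",
    "chronic_liver_disease",
    "viral_hepatitis",
    "parkinsons_disease",
]

N_CONDITIONS = len(DEFAULT_CONDITIONS)


def condition_columns(n: int = N_CONDITIONS) -> list[str]:
    """CSV column names ``cond_01`` ... ``cond_<n>``."""
    return [f"cond_{j + 1:02d}" for j in range(n)]
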