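"""Design construction: dummy coding of baseline covariates and the
(X, Z, u) rows of the mixed sub-model.

Categorical covariates are expanded by reference-cell coding with the
study's reference categories: female, rural residence (so urban carries
its own indicator), no-comorbidity, monotherapy regimen and enalapril.
The time design of each marker is always X = Z = (1, t) with t in months
since enrolment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError
from .params import DesignSpec

#: raw categorical columns and the dummy columns they expand to
CATEGORY_CODING = {
    "sex": {"female": (), "male": ("sex_male",)},
    "residence": {"rural": (), "urban": ("residence_urban",)},
    "regimen": {
        "monotherapy": (),
        "two_drug": ("regimen_two",),
        "three_plus": ("regimen_three_plus",),
    },
    "drug_type": {
        "enalapril": (),
        "nifedipine": ("drug_nifedipine",),
        "both": ("drug_both",),
        "other": ("drug_other",),
    },
}
DUMMY_COLUMNS = tuple(
    d for coding in CATEGORY_CODING.values() for cats in coding.values() for d in cats
)
BINARY_COLUMNS = ("dm", "ckd", "stroke", "hiv")
CONTINUOUS_COLUMNS = (
    "age",
    "bcl",
    "gbl",
    "bun",
    "creatinine",
    "calcium",
    "sodium",
    "potassium",
    "chlorine",
    "hemoglobin",
)


def expand_baseline(cohort: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code the categorical baseline covariates.

    Returns a numeric frame indexed like ``cohort`` containing the
    continuous columns, the 0/1 comorbidity indicators and one indicator
    per non-reference category.
    """
    out = pd.DataFrame(index=cohort.index)
    for col, coding in CATEGORY_CODING.items():
        if col not in cohort.columns:
            continue
        values = cohort[col].astype(str)
        unknown = set(values.unique()) - set(coding)
        if unknown:
            raise SchemaError(f"unknown categories {sorted(unknown)} in column {col!r}")
        for cat, dummies in coding.items():
            for d in dummies:
                out[d] = (values == cat).astype(float)
    for col in BINARY_COLUMNS + CONTINUOUS_COLUMNS:
        if col in cohort.columns:
            out[col] = pd.to_numeric(cohort[col], errors="raise").astype(float)
    return out


def covariate_matrix(cohort: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    """Extract an (n, p) matrix of expanded covariates in ``names`` order."""
    expanded = expand_baseline(cohort)
    missing = [c for c in names if c not in expanded.columns]
    if missing:
        raise SchemaError(f"covariates {missing} not found in baseline table")
    if not names:
        return np.empty((len(cohort), 0))
    return expanded[list(names)].to_numpy(dtype=float)


def build_design(row: pd.Series | dict, time: float, spec: DesignSpec):
    """Design rows for one subject at one time.

    Returns ``{"sbp": (X, Z, u), "dbp": (X, Z, u)}`` with X = Z = (1, t)
    and u the expanded covariate row in ``spec`` order for that marker.
    """
    frame = pd.DataFrame([dict(row)])
    xz = np.array([1.0, float(time)])
    return {
        "sbp": (xz.copy(), xz.copy(), covariate_matrix(frame, spec.sbp_covariates)[0]),
        "dbp": (xz.copy(), xz.copy(), covariate_matrix(frame, spec.dbp_covariates)[0]),
    }
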