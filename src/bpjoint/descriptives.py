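"""Descriptive statistics layer: baseline-by-outcome contingency tables
with chi-square association tests, cohort summaries, and the study-design
sample-size formula for a survival endpoint.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .design import BINARY_COLUMNS, CATEGORY_CODING, CONTINUOUS_COLUMNS
from .errors import ConfigurationError, SchemaError


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    corrected: bool
    expected: np.ndarray


def chi_square_association(counts, correction: str | bool = "auto") -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction='auto'`` applies the Yates continuity correction exactly
    when the table is 2x2 (the convention of the study's descriptive
    tables); pass True/False to force it on or off.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ConfigurationError("counts must be a table with >= 2 rows and columns")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ConfigurationError("counts must be non-negative integers")
    rows, cols = counts.sum(axis=1), counts.sum(axis=0)
    if np.any(rows == 0):
        raise ConfigurationError(f"row margin {int(np.argmin(rows))} is zero")
    if np.any(cols == 0):
        raise ConfigurationError(f"column margin {int(np.argmin(cols))} is zero")
    if correction == "auto":
        use = counts.shape == (2, 2)
    else:
        use = bool(correction) and counts.shape == (2, 2)
    res = stats.chi2_contingency(counts, correction=use)
    return ContingencyResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        corrected=use,
        expected=np.asarray(res.expected_freq),
    )


def _percent(x: float) -> float:
    """Half-up rounding to one decimal, as printed in descriptive tables."""
    return float(Decimal(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def baseline_summary(cohort: pd.DataFrame, survival: pd.DataFrame):
    """Baseline frequencies split by censored vs event, with chi-square tests.

    Returns ``(categorical, continuous)``: the first frame has one row per
    covariate category with counts and percentages of the total cohort by
    outcome plus the covariate-level chi-square statistic/p-value; the
    second has mean and SD per continuous covariate.
    """
    if set(cohort["id"]) != set(survival["id"]):
        raise SchemaError("baseline and survival tables must cover the same ids")
    merged = cohort.merge(survival[["id", "event"]], on="id", validate="one_to_one")
    n = len(merged)
    rows = []
    covariates = [c for c in CATEGORY_CODING if c in merged.columns]
    covariates += [c for c in BINARY_COLUMNS if c in merged.columns]
    for cov in covariates:
        values = merged[cov].map({0: "no", 1: "yes"}) if cov in BINARY_COLUMNS else merged[cov]
        cats = (
            list(CATEGORY_CODING[cov]) if cov in CATEGORY_CODING else ["yes", "no"]
        )
        cats = [c for c in cats if (values == c).any()] + sorted(
            set(values.unique()) - set(cats)
        )
        table = np.array(
            [
                [int(((values == c) & (merged["event"] == e)).sum()) for e in (0, 1)]
                for c in cats
            ]
        )
        test = None
        if table.shape[0] >= 2 and np.all(table.sum(axis=1) > 0) and np.all(table.sum(axis=0) > 0):
            test = chi_square_association(table)
        for c, (cens, ev) in zip(cats, table):
            rows.append(
                {
                    "covariate": cov,
                    "category": c,
                    "censored": cens,
                    "censored_pct": _percent(100.0 * cens / n),
                    "event": ev,
                    "event_pct": _percent(100.0 * ev / n),
                    "total": cens + ev,
                    "total_pct": _percent(100.0 * (cens + ev) / n),
                    "chi_square": test.statistic if test else np.nan,
                    "p_value": test.p_value if test else np.nan,
                }
            )
    categorical = pd.DataFrame(rows)
    cont = [c for c in CONTINUOUS_COLUMNS if c in merged.columns]
    continuous = pd.DataFrame(
        {
            "covariate": cont,
            "mean": [merged[c].mean() for c in cont],
            "sd": [merged[c].std(ddof=1) for c in cont],
        }
    )
    return categorical, continuous


def required_sample_size(alpha: float, power: float, p_event: float, log_hr: float) -> int:
    """Smallest n with adequate power to detect a log hazard ratio.

    Uses n = 4 (z_{alpha/2} + z_{power})^2 / (p * theta^2), where p is the
    anticipated event probability and theta the log hazard ratio, rounded
    up to the next integer.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    if not 0 < p_event <= 1:
        raise ConfigurationError("event probability must lie in (0, 1]")
    if log_hr == 0:
        raise ConfigurationError("log hazard ratio of 0 implies an infinite sample size")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return int(np.ceil(4.0 * z**2 / (p_event * log_hr**2)))
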