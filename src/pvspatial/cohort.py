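"""Biomarker classification and demographic summary statistics.

Amyloid positivity is classified from cortical SUVR with tracer-specific
thresholds (1.11 for florbetapir/FBP, 1.08 for florbetaben/FBB;
comparison inclusive).  APOE-e4 status is positive with at least one e4
allele.  Demographic tables compare groups with Pearson chi-squared tests
(no continuity correction) for categorical variables and two-sided
pooled-variance Student t-tests for continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SUVR_THRESHOLDS",
    "classify_amyloid",
    "classify_apoe",
    "cell_percentage",
    "chi_squared_test",
    "demographic_tests",
    "CohortSummary",
    "VariableSummary",
]

SUVR_THRESHOLDS = {"FBP": 1.11, "FBB": 1.08}


def classify_amyloid(suvr: float, tracer: str) -> str:
    """'positive' iff SUVR >= the tracer threshold (1.11 FBP, 1.08 FBB)."""
    if not suvr > 0:
        raise ValueError(f"SUVR must be positive, got {suvr}")
    try:
        threshold = SUVR_THRESHOLDS[tracer.upper()]
    except KeyError:
        raise ValueError(f"unknown tracer {tracer!r}; expected FBP or FBB") from None
    return "positive" if suvr >= threshold else "negative"


def classify_apoe(genotype) -> str:
    """'carrier' iff the allele pair contains at least one e4."""
    alleles = [str(a).strip().lower().replace("ε", "e") for a in genotype]
    if len(alleles) != 2 or any(a not in {"e2", "e3", "e4"} for a in alleles):
        raise ValueError(f"malformed APOE genotype: {genotype!r}")
    return "carrier" if "e4" in alleles else "non_carrier"


def cell_percentage(count: int, denominator: int) -> float:
    """100*count/denominator, half-up rounded to 2 decimals (table format)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count < 0 or count > denominator:
        raise ValueError(f"count {count} outside [0, {denominator}]")
    pct = Decimal(100 * count) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def chi_squared_test(table: np.ndarray) -> tuple[float, float, bool]:
    """Pearson chi-squared on a contingency table, no continuity correction.

    Returns (statistic, p, reliable); reliable is False when any expected
    cell count is zero, in which case the test result is flagged rather
    than suppressed.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    row = tab.sum(axis=1, keepdims=True)
    col = tab.sum(axis=0, keepdims=True)
    expected = row @ col / tab.sum()
    if np.any(expected == 0):
        return float("nan"), float("nan"), False
    stat = float(((tab - expected) ** 2 / expected).sum())
    dof = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return stat, float(sps.chi2.sf(stat, dof)), True


@dataclass
class VariableSummary:
    """Per-variable cross-group summary with its test."""

    variable: str
    kind: str  # categorical | continuous
    cells: dict[str, dict]  # group -> {level: (count, pct)} or {mean, sd, n}
    statistic: float
    p_value: float
    reliable: bool = True
    pairwise: dict[tuple[str, str], tuple[float, float]] | None = None


@dataclass
class CohortSummary:
    """Demographic table machinery: one VariableSummary per variable."""

    group_col: str
    group_n: dict[str, int]
    variables: list[VariableSummary]


def _categorical_summary(df: pd.DataFrame, var: str, group_col: str, groups) -> VariableSummary:
    sub = df[[group_col, var]].dropna()
    levels = sorted(sub[var].astype(str).unique())
    table = np.array(
        [
            [int(((sub[group_col] == g) & (sub[var].astype(str) == lv)).sum()) for lv in levels]
            for g in groups
        ]
    )
    stat, p, reliable = chi_squared_test(table.T) if table.shape[1] >= 2 else (np.nan, np.nan, False)
    cells = {}
    for gi, g in enumerate(groups):
        denom = int(table[gi].sum())  # group n minus missing for this variable
        cells[g] = {
            lv: (int(table[gi, li]), cell_percentage(int(table[gi, li]), denom) if denom else np.nan)
            for li, lv in enumerate(levels)
        }
    return VariableSummary(var, "categorical", cells, stat, p, reliable)


def _continuous_summary(
    df: pd.DataFrame, var: str, group_col: str, groups, equal_var: bool
) -> VariableSummary:
    sub = df[[group_col, var]].dropna()
    samples = {g: sub.loc[sub[group_col] == g, var].astype(float).values for g in groups}
    cells = {
        g: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "n": len(v)}
        for g, v in samples.items()
    }
    pairwise = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            t, p = sps.ttest_ind(samples[a], samples[b], equal_var=equal_var)
            pairwise[(a, b)] = (float(t), float(p))
    # headline statistic: the first pairwise test (2 groups) or min pairwise p
    if len(groups) == 2:
        stat, p = pairwise[(groups[0], groups[1])]
    else:
        stat, p = min(pairwise.values(), key=lambda tp: tp[1])
    return VariableSummary(var, "continuous", cells, stat, p, True, pairwise)


def demographic_tests(
    df: pd.DataFrame,
    group_col: str,
    categorical: list[str] = (),
    continuous: list[str] = (),
    equal_var: bool = True,
) -> CohortSummary:
    """Build the demographic comparison table for one grouping.

    Percentages use the group n minus missing for each variable as the
    denominator.  ``equal_var=False`` switches the t-tests to Welch.
    """
    groups = [g for g in df[group_col].dropna().unique()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any((df[group_col] == g).sum() < 2 for g in groups):
        raise ValueError("each group needs at least two rows")
    variables = [_categorical_summary(df, v, group_col, groups) for v in categorical]
    variables += [_continuous_summary(df, v, group_col, groups, equal_var) for v in continuous]
    return CohortSummary(
        group_col=group_col,
        group_n={g: int((df[group_col] == g).sum()) for g in groups},
        variables=variables,
    )
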