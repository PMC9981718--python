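"""Set-comparability battery and the univariate biomarker screen.

Two pre-clustering checks on the cohort:

* :func:`compare_sets` verifies that the training and validation sets are
  demographically comparable — Welch t-test for age, Pearson chi-squared
  (Yates-corrected for 2x2 tables) for the nominal/ordinal variables.
* :func:`univariate_screen` relates every biomarker to every demographic or
  clinical variable — regression-slope test against age, one-way ANOVA
  against ordinal scores, t-test against binary variables — with a
  Bonferroni column over the full family of tests (10 biomarkers x 7
  clinical variables = 70 tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Cohort, TRAINING, VALIDATION

__all__ = [
    "ComparabilityRow",
    "ScreenResult",
    "chi_squared_test",
    "welch_t_test",
    "compare_sets",
    "univariate_screen",
    "bonferroni",
]


@dataclass(frozen=True)
class ComparabilityRow:
    variable: str
    test: str  # "t-test" | "chi-squared"
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ScreenResult:
    biomarker: str
    clinical_variable: str
    test: str  # "linear_regression" | "anova" | "t_test"
    statistic: float
    p_raw: float
    p_bonferroni: float


def chi_squared_test(table, continuity: bool = True) -> tuple[float, float]:
    """Pearson chi-squared on an r x c contingency table.

    Yates continuity correction (|O-E| shrunk by 0.5, floored at 0) is
    applied iff ``continuity`` and the table is 2x2; df = (r-1)(c-1).

    Raises
    ------
    ValueError
        Negative or non-integer cells, a zero row/column margin, or fewer
        than 2 rows/columns.
    """
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row/column margin")
    correction = bool(continuity) and table.shape == (2, 2)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test (Welch-Satterthwaite df)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_sets(cohort: Cohort) -> list[ComparabilityRow]:
    """Training-vs-validation comparability battery.

    One test per demographic / clinical / outcome / group variable: Welch
    t-test for continuous variables (age), chi-squared otherwise (with the
    Yates correction whenever the observed table collapses to 2x2).
    """
    schema = cohort.schema
    train, val = cohort.split()
    if train.empty or val.empty:
        raise ValueError("both sets must be non-empty")
    rows: list[ComparabilityRow] = []
    names = (
        schema.by_role("demographic")
        + schema.by_role("clinical_score")
        + schema.by_role("outcome_score")
        + schema.by_role("group_label")
    )
    for name in names:
        var = schema[name]
        if var.scale == "continuous":
            t, p = welch_t_test(train[name], val[name])
            rows.append(ComparabilityRow(name, "t-test", t, p))
        else:
            levels = sorted(set(cohort.data[name].dropna().unique()))
            if len(levels) < 2:
                raise ValueError(f"variable {name!r} is constant across the cohort")
            table = np.array(
                [
                    [(train[name] == lv).sum() for lv in levels],
                    [(val[name] == lv).sum() for lv in levels],
                ]
            )
            chi2, p = chi_squared_test(table, continuity=True)
            rows.append(ComparabilityRow(name, "chi-squared", chi2, p))
    return rows


def bonferroni(p_raw: float, m: int) -> float:
    """Family-wise corrected p-value, min(1, m * p)."""
    return min(1.0, m * p_raw)


def univariate_screen(cohort: Cohort) -> list[ScreenResult]:
    """Biomarker-by-clinical-variable screen with Bonferroni correction.

    For each biomarker: regression-slope t-test against continuous
    variables, one-way ANOVA across ordinal score levels (empty levels are
    dropped with a warning), Welch t-test against binary variables.  The
    Bonferroni factor m is the total number of tests performed.
    """
    schema = cohort.schema
    clinical = (
        schema.by_role("demographic")
        + schema.by_role("clinical_score")
        + schema.by_role("outcome_score")
        + schema.by_role("group_label")
    )
    raw: list[tuple[str, str, str, float, float]] = []
    for marker in schema.biomarkers:
        y = cohort.data[marker].to_numpy(dtype=float)
        for name in clinical:
            var = schema[name]
            x = cohort.data[name].to_numpy(dtype=float)
            if var.scale == "continuous":
                res = stats.linregress(x, y)
                raw.append((marker, name, "linear_regression", res.slope / res.stderr, res.pvalue))
            elif var.scale == "binary":
                t, p = welch_t_test(y[x == 1], y[x == 0])
                raw.append((marker, name, "t_test", t, p))
            else:
                groups = []
                for lv in var.levels:
                    g = y[x == lv]
                    if g.size == 0:
                        warnings.warn(
                            f"{name!r}: level {lv} absent from the data; dropped",
                            stacklevel=2,
                        )
                    else:
                        groups.append(g)
                f, p = stats.f_oneway(*groups)
                raw.append((marker, name, "anova", float(f), float(p)))
    m = len(raw)
    return [
        ScreenResult(b, c, test, stat, p, bonferroni(p, m))
        for b, c, test, stat, p in raw
    ]


def screen_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular view of the screen, one row per test."""
    return pd.DataFrame([r.__dict__ for r in results])
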