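"""Univariate cohort comparisons (risk-factor table machinery).

Continuous variables are compared with the independent two-sample
Student's t test (pooled variance by default, Welch togglable) — either
from raw vectors or directly from printed (n, mean, SD) summaries.
Categorical risk factors use the Pearson chi-square test on 2x2 counts
(continuity correction off by default, matching large-sample usage).
No multiple-testing correction is applied, deliberately mirroring how
such univariate tables are conventionally reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupSummary:
    """Printed summary of one group: n, mean, SD."""

    n: int
    mean: float
    sd: float

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")

    @classmethod
    def of(cls, values) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(arr.size, float(arr.mean()), float(arr.std(ddof=1)))


@dataclass
class UnivariateResult:
    variable: str
    statistic: float
    p_value: float
    test_kind: str
    defined: bool = True


def student_t_raw(a, b, variable: str = "", welch: bool = False) -> UnivariateResult:
    """Two-sided independent t test on raw vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    kind = "welch_t" if welch else "student_t"
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return UnivariateResult(variable, 0.0, 1.0, kind)
        return UnivariateResult(
            variable, math.inf * np.sign(b.mean() - a.mean()), math.nan, kind, False
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return UnivariateResult(variable, float(t), float(p), kind)


def student_t_summary(
    a: GroupSummary, b: GroupSummary, variable: str = "", welch: bool = False
) -> UnivariateResult:
    """Two-sided independent t test from (n, mean, SD) summaries only."""
    a.validate()
    b.validate()
    kind = "welch_t" if welch else "student_t"
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return UnivariateResult(variable, 0.0, 1.0, kind)
        return UnivariateResult(
            variable, math.inf * np.sign(b.mean - a.mean), math.nan, kind, False
        )
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    return UnivariateResult(variable, float(t), float(p), kind)


def chi_square_2x2(
    a_yes: int, a_no: int, b_yes: int, b_no: int,
    variable: str = "", correction: bool = False,
) -> UnivariateResult:
    """Pearson chi-square on a 2x2 table of group x yes/no counts."""
    table = np.array([[a_yes, a_no], [b_yes, b_no]])
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    res = stats.chi2_contingency(table, correction=correction)
    return UnivariateResult(variable, float(res.statistic), float(res.pvalue), "chi_square")


def compare_groups(
    cohort: pd.DataFrame,
    group_col: str = "group",
    variables: list[str] | None = None,
    welch: bool = False,
    correction: bool = False,
) -> pd.DataFrame:
    """Risk-factor-table style comparison of two cohort groups.

    Numeric columns get the t test and are summarized mean +/- SD;
    yes/no columns get the chi-square test and are summarized n (%).
    Returns one row per variable with per-group summaries, the
    statistic, p-value and test kind.
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    ga, gb = groups
    sub_a = cohort[cohort[group_col] == ga]
    sub_b = cohort[cohort[group_col] == gb]
    if variables is None:
        variables = [
            c for c in cohort.columns
            if c not in (group_col, "patient_id")
        ]
    rows = []
    for var in variables:
        col = cohort[var]
        if pd.api.types.is_numeric_dtype(col):
            a, b = sub_a[var].to_numpy(float), sub_b[var].to_numpy(float)
            res = student_t_raw(a, b, variable=var, welch=welch)
            fmt_a = f"{a.mean():.2f} ± {a.std(ddof=1):.2f}"
            fmt_b = f"{b.mean():.2f} ± {b.std(ddof=1):.2f}"
        else:
            ay = int((sub_a[var] == "yes").sum())
            by = int((sub_b[var] == "yes").sum())
            res = chi_square_2x2(
                ay, len(sub_a) - ay, by, len(sub_b) - by,
                variable=var, correction=correction,
            )
            fmt_a = f"{ay} ({100 * ay / len(sub_a):.0f}%)"
            fmt_b = f"{by} ({100 * by / len(sub_b):.0f}%)"
        rows.append((var, fmt_a, fmt_b, res.statistic, res.p_value, res.test_kind))
    return pd.DataFrame(
        rows, columns=["variable", ga, gb, "statistic", "p_value", "test_kind"]
    )
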