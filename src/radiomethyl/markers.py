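"""Pyrosequencing-style marker evaluation.

A gene's promoter methylation is summarized as the arithmetic mean over
its pyrosequenced CpG positions. Candidate markers are kept when that
mean exceeds a positivity threshold (default 5%, strict) in every
specimen class tested — the rule that narrows a discovery panel to the
genes measurable above background in blood and vascular tissue alike.
Tissue contrasts use the paired t test (same-donor non-plaque vs plaque
intima) and one-way ANOVA (three or more specimen classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MarkerSelection:
    selected: list[str]
    not_selected: list[str]
    non_evaluable: list[str]


def gene_mean(per_cpg: list[float] | np.ndarray) -> float:
    """Mean methylation over all pyrosequenced CpG sites of one assay."""
    arr = np.asarray(per_cpg, dtype=float)
    if arr.size == 0:
        raise ValueError("no CpG values")
    return float(arr.mean())


def select_positive_genes(
    panel: pd.DataFrame, threshold: float = 5.0, per_specimen: pd.DataFrame | None = None
) -> MarkerSelection:
    """Apply the strict >threshold positivity rule across specimen classes.

    ``panel`` is a gene x specimen-class table of mean methylation
    percentages. A gene is selected when its value exceeds ``threshold``
    in EVERY class; genes with any missing cell are reported as
    non-evaluable rather than silently dropped.

    With ``per_specimen`` given (long table with ``gene`` and
    ``gene_mean`` per specimen), the stricter every-single-specimen
    semantics is applied instead.
    """
    if per_specimen is not None:
        grp = per_specimen.groupby("gene")["gene_mean"]
        selected = sorted(g for g, s in grp if (s > threshold).all())
        evaluable = set(grp.groups)
        return MarkerSelection(
            selected,
            sorted(evaluable - set(selected)),
            sorted(set(panel.index) - evaluable),
        )
    non_evaluable = sorted(panel.index[panel.isna().any(axis=1)])
    evaluable = panel.dropna()
    mask = (evaluable > threshold).all(axis=1)
    return MarkerSelection(
        sorted(evaluable.index[mask]),
        sorted(evaluable.index[~mask]),
        non_evaluable,
    )


@dataclass
class TestResult:
    statistic: float
    p_value: float
    defined: bool = True


def paired_t(values_a, values_b) -> TestResult:
    """Two-sided paired Student's t on same-specimen differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = a - b
    # zero variance up to float jitter (e.g. an exactly constant shift)
    if np.std(d, ddof=1) <= 1e-10 * max(1.0, float(np.abs(d).max())):
        if np.allclose(d, 0):
            return TestResult(0.0, 1.0)
        # constant nonzero shift: t diverges, p undefined
        return TestResult(math.inf * np.sign(d[0]), math.nan, defined=False)
    t, p = stats.ttest_rel(a, b)
    return TestResult(float(t), float(p))


def one_way_anova(*groups) -> TestResult:
    """One-way fixed-effects ANOVA across three or more groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA here compares at least three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # zero within- and between-group variance
        return TestResult(math.nan, math.nan, defined=False)
    return TestResult(float(f), float(p))
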