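"""Cohort descriptive statistics: group comparisons in clinical-table form.

Each variable is compared between the overweight and obese groups with a
pooled-variance two-sample Student's t (direction: overweight minus obese,
df = n0 + n1 − 2, two-sided p). Binary variables are coded 0/1 on a stated
reference level (male = 1 for sex, American = 1 for diet) and summarized
both as level counts and as coded means; a Welch variant is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from braingut.cohort import SyntheticCohort

__all__ = ["ComparisonRow", "group_comparison", "table_from_counts", "make_cohort_table"]


@dataclass
class ComparisonRow:
    """One clinical-table row: group summaries plus the t test."""

    variable: str
    mean_overweight: float
    sd_overweight: float
    mean_obese: float
    sd_obese: float
    t: float
    p: float
    df: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def group_comparison(
    overweight_values, obese_values, variable: str = "", welch: bool = False
) -> ComparisonRow:
    """Two-sample t comparison of a per-subject variable between groups.

    Uses the pooled-variance Student's t with sample variances (n−1
    denominator) by default; ``welch=True`` switches to the
    unequal-variance form. Direction is overweight minus obese.
    """
    a = np.asarray(overweight_values, dtype=float)
    b = np.asarray(obese_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError(f"zero pooled variance for {variable!r}")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = len(a) + len(b) - 2 if not welch else float(res.df)
    return ComparisonRow(
        variable=variable,
        mean_overweight=float(a.mean()),
        sd_overweight=float(a.std(ddof=1)),
        mean_obese=float(b.mean()),
        sd_obese=float(b.std(ddof=1)),
        t=float(res.statistic),
        p=float(res.pvalue),
        df=int(df) if not welch else df,
    )


def table_from_counts(
    n_positive_overweight: int,
    n_overweight: int,
    n_positive_obese: int,
    n_obese: int,
    variable: str = "",
    welch: bool = False,
) -> ComparisonRow:
    """Group comparison of a binary variable given only its level counts.

    Reconstructs the 0/1-coded per-subject vectors (e.g. sex with male = 1)
    and applies :func:`group_comparison`; with printed clinical-table
    compositions this reproduces the table's t statistic exactly.
    """
    a = np.array([1] * n_positive_overweight + [0] * (n_overweight - n_positive_overweight))
    b = np.array([1] * n_positive_obese + [0] * (n_obese - n_positive_obese))
    return group_comparison(a, b, variable=variable, welch=welch)


def make_cohort_table(cohort: SyntheticCohort, welch: bool = False) -> pd.DataFrame:
    """Clinical-characteristics table for a synthetic cohort.

    Rows: age (years), sex (male = 1) and diet (American = 1), each with
    group means/SDs and the two-sample t test (overweight minus obese).
    """
    over = cohort.labels == 0
    obese = cohort.labels == 1
    rows = []
    for var in ("age", "sex", "diet"):
        values = cohort.covariates[var]
        rows.append(
            group_comparison(values[over], values[obese], variable=var, welch=welch).as_dict()
        )
    return pd.DataFrame(rows).set_index("variable")
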