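"""Demographic and clinical comparisons (Table-1-style statistics).

Two-sample t-tests operating directly on summary statistics (mean, SD,
n per group -- the form in which cohort tables are published),
chi-squared tests on 2x2 contingency tables (e.g. sex by group), and a
two-way mixed-design repeated-measures ANOVA (between-subject group
factor, within-subject time factor) for scores measured at baseline and
follow-up.

With only two timepoints sphericity holds trivially, so no correction
is applied to the within-subject F tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError


@dataclass(frozen=True)
class GroupSummary:
    """Published-form summary of one group: mean (SD), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DataError(f"SD must be nonnegative, got {self.sd}")
        if self.n < 2:
            raise DataError(f"need n >= 2, got {self.n}")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 contingency table of counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d < 1:
            raise DataError("grand total must be at least 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def t_test_from_summary(
    s1: GroupSummary, s2: GroupSummary, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from group summaries.

    Returns (t, df, two-tailed p).  ``pooled=True`` uses the classic
    Student pooled-variance test; the default is Welch's unequal-variance
    test with Satterthwaite degrees of freedom.
    """
    if s1.sd == 0 and s2.sd == 0 and s1.mean == s2.mean:
        raise DataError("zero variance in both groups with equal means: t undefined")
    res = stats.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=pooled
    )
    if pooled:
        df = s1.n + s2.n - 2
    else:
        v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(tab: TwoByTwo, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test (1 df) on a 2x2 table.

    Continuity correction is off by default; pass ``yates=True`` to
    enable it.  Raises on a zero marginal (the statistic is undefined).
    """
    arr = tab.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DataError("chi-squared undefined: a row or column marginal is zero")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=yates)
    assert dof == 1
    return float(chi2), float(p)


@dataclass(frozen=True)
class MixedAnovaResult:
    """F tests and sum-of-squares decomposition of a 2x2 mixed design."""

    f_group: float
    p_group: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    df_between: tuple[float, float]
    df_within: tuple[float, float]
    ss: dict[str, float]


def repeated_anova(
    data: pd.DataFrame,
    value: str = "value",
    subject: str = "subject_id",
    group: str = "group",
    time: str = "timepoint",
) -> MixedAnovaResult:
    """Two-way mixed-design ANOVA: between-subject group, within-subject time.

    Expects long-format data with exactly two timepoints per subject and
    two groups.  The classical decomposition is used:

    * between-subject: SS_group tested against SS_subjects-within-groups,
    * within-subject: SS_time and SS_group:time tested against the
      time-by-subject residual.

    The sums of squares partition SS_total exactly.
    """
    df = data[[subject, group, time, value]].copy()
    counts = df.groupby([subject], observed=True)[time].nunique()
    if (counts != 2).any():
        bad = counts[counts != 2].index.tolist()
        raise DataError(f"subjects without both timepoints: {bad[:5]}")
    groups = df[group].unique()
    times = sorted(df[time].unique())
    if len(groups) != 2 or len(times) != 2:
        raise DataError("design must have exactly 2 groups and 2 timepoints")
    g_of = df.groupby(subject, observed=True)[group].nunique()
    if (g_of != 1).any():
        raise DataError("a subject appears in more than one group")

    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    n_t = len(times)
    ss_total = ((y - grand) ** 2).sum()

    subj_means = df.groupby(subject, observed=True)[value].mean()
    ss_between_subj = n_t * ((subj_means - grand) ** 2).sum()
    ss_within_subj = ss_total - ss_between_subj

    grp_of_subj = df.groupby(subject, observed=True)[group].first()
    n_per_group = grp_of_subj.value_counts()
    grp_means = df.groupby(group, observed=True)[value].mean()
    ss_group = sum(
        n_per_group[g] * n_t * (grp_means[g] - grand) ** 2 for g in groups
    )
    ss_subj_within = ss_between_subj - ss_group

    time_means = df.groupby(time, observed=True)[value].mean()
    n_subjects = len(subj_means)
    ss_time = sum(n_subjects * (time_means[t] - grand) ** 2 for t in times)

    cell_means = df.groupby([group, time], observed=True)[value].mean()
    ss_inter = sum(
        n_per_group[g] * (cell_means[(g, t)] - grp_means[g] - time_means[t] + grand) ** 2
        for g in groups
        for t in times
    )
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = 1.0, float(n_subjects - 2)
    df_time, df_err = 1.0, float(n_subjects - 2)
    if df_subj <= 0:
        raise DataError("need at least 3 subjects for the mixed ANOVA")

    def f_and_p(ss_eff, df_eff, ss_err, df_error):
        ms_err = ss_err / df_error
        if ms_err == 0:
            return (0.0, 1.0) if ss_eff == 0 else (np.inf, 0.0)
        f = (ss_eff / df_eff) / ms_err
        return float(f), float(stats.f.sf(f, df_eff, df_error))

    f_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_subj)
    f_t, p_t = f_and_p(ss_time, df_time, ss_err_within, df_err)
    f_i, p_i = f_and_p(ss_inter, df_time, ss_err_within, df_err)
    return MixedAnovaResult(
        f_group=f_g,
        p_group=p_g,
        f_time=f_t,
        p_time=p_t,
        f_interaction=f_i,
        p_interaction=p_i,
        df_between=(df_group, df_subj),
        df_within=(df_time, df_err),
        ss={
            "total": float(ss_total),
            "between_subjects": float(ss_between_subj),
            "within_subjects": float(ss_within_subj),
            "group": float(ss_group),
            "subjects_within_groups": float(ss_subj_within),
            "time": float(ss_time),
            "group_x_time": float(ss_inter),
            "error_within": float(ss_err_within),
        },
    )


def demographic_report(
    rows: list[dict],
) -> pd.DataFrame:
    """Assemble a Table-1-style report from per-variable test results.

    Each row dict needs: variable, group1, group2 (formatted "mean (SD)"
    or counts), test, statistic, p.
    """
    return pd.DataFrame(
        rows, columns=["variable", "group1", "group2", "test", "statistic", "p"]
    )
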