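"""Condition comparisons: two-sample Student's t with significance stars.

The default is the classical pooled-variance two-sample t-test with a
two-sided p value, the test conventionally reported for focus-mobility and
recruitment comparisons; Welch's unequal-variance variant is available by
flag.  Stars: p < 0.05 "*", p < 0.01 "**", p < 0.001 "***", otherwise "ns".
No multiple-testing correction is applied (comparison counts are reported
so users can apply their own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TTestResult", "ConditionSummary", "compare_groups", "summarize",
           "compare_all", "stars", "DegenerateGroupsError"]


class DegenerateGroupsError(ValueError):
    """Both groups have zero variance but different means: the t statistic
    is infinite and the classical test is undefined."""


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TTestResult:
    t: float
    p: float
    stars: str
    n_a: int
    n_b: int
    df: float
    equal_var: bool


@dataclass
class ConditionSummary:
    """Per-condition summary: mean, SD (as printed alongside figures), n."""

    condition: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not np.isfinite(self.mean):
            raise ValueError("mean must be finite")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def compare_groups(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sample two-sided Student's t-test (pooled variance by default).

    Degenerate input (zero variance in both groups): equal means give
    t = 0, p = 1; unequal means raise :class:`DegenerateGroupsError`.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must be finite")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            dof = len(a) + len(b) - 2 if equal_var else np.nan
            return TTestResult(0.0, 1.0, "ns", len(a), len(b), dof, equal_var)
        raise DegenerateGroupsError(
            "zero variance in both groups with unequal means")

    res = sps.ttest_ind(a, b, equal_var=equal_var)
    dof = len(a) + len(b) - 2 if equal_var else float(res.df)
    t, p = float(res.statistic), float(res.pvalue)
    return TTestResult(t, p, stars(p), len(a), len(b), dof, equal_var)


def summarize(df: pd.DataFrame, groupby: str, measure: str) -> list[ConditionSummary]:
    """Mean, SD, and n of ``measure`` per level of ``groupby``."""
    out = []
    for label, sub in df.groupby(groupby, sort=True):
        vals = sub[measure].to_numpy(float)
        out.append(ConditionSummary(
            condition=str(label), n=len(vals), mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0))
    return out


def compare_all(df: pd.DataFrame, groupby: str, measure: str,
                equal_var: bool = True) -> pd.DataFrame:
    """All pairwise group comparisons as a tidy table
    (group_a, group_b, t, p, stars, n_a, n_b)."""
    labels = sorted(df[groupby].unique())
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            r = compare_groups(df.loc[df[groupby] == la, measure],
                               df.loc[df[groupby] == lb, measure],
                               equal_var=equal_var)
            rows.append({"group_a": la, "group_b": lb, "t": r.t, "p": r.p,
                         "stars": r.stars, "n_a": r.n_a, "n_b": r.n_b})
    return pd.DataFrame(rows)
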