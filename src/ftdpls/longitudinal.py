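"""Yearly rates of change of latent-variable scores and their group tests.

A patient with a baseline and a follow-up visit contributes, per LV and
block, a yearly rate

    rate = (follow-up score - baseline score) / interval in years

Within-cohort change is tested with two-sided paired t-tests on the raw
score differences; rates are compared across the three variants with all
pairwise two-sample t-tests under Tukey-Kramer familywise correction
(studentized-range distribution, pooled within-group variance, so the
procedure is exact for unequal group sizes under the classical ANOVA
assumptions; Welch statistics are available by flag for unequal variances).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RateRecord", "yearly_rate", "rate_table", "paired_change_test",
           "PairedTestResult", "group_rate_contrasts"]


@dataclass
class RateRecord:
    subject_id: str
    lv: str
    block: str              # "score_x" or "score_y"
    baseline: float
    followup: float
    interval: float         # years, > 0
    rate: float             # score units per year


def yearly_rate(baseline, followup, interval_years):
    """(follow-up - baseline) / interval; vectorized, interval must be > 0."""
    base = np.asarray(baseline, dtype=float)
    fu = np.asarray(followup, dtype=float)
    iv = np.asarray(interval_years, dtype=float)
    if np.any(iv <= 0):
        raise ValueError("interval_years must be > 0")
    return (fu - base) / iv


def rate_table(base_scores: pd.DataFrame, fu_scores: pd.DataFrame,
               intervals: pd.Series) -> pd.DataFrame:
    """Build RateRecords from subject-indexed baseline/follow-up score frames.

    All three inputs must be indexed by subject id; the join is keyed on
    that index so shuffled or orphaned follow-up rows raise instead of
    silently mis-pairing.
    """
    fu_subjects = fu_scores.index
    missing = fu_subjects.difference(base_scores.index)
    if len(missing):
        raise KeyError(f"follow-up subjects without baseline scores: {list(missing)[:5]}")
    missing_iv = fu_subjects.difference(intervals.index)
    if len(missing_iv):
        raise KeyError(f"follow-up subjects without intervals: {list(missing_iv)[:5]}")
    base = base_scores.loc[fu_subjects]
    iv = intervals.loc[fu_subjects].astype(float)
    rows = []
    for col in fu_scores.columns:
        r = yearly_rate(base[col], fu_scores[col], iv)
        for sid, b, f, t, rate in zip(fu_subjects, base[col], fu_scores[col], iv, r):
            rows.append({"subject_id": sid, "score": col, "baseline": b,
                         "followup": f, "interval": t, "rate": rate})
    return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    t: float
    p: float
    n: int
    mean_change: float
    degenerate: bool = False


def paired_change_test(baseline, followup) -> PairedTestResult:
    """Two-sided paired t-test on follow-up minus baseline differences.

    Identical vectors (no change anywhere) return t=0, p=1 with the
    degenerate flag set; zero-variance differences with a non-zero mean
    leave p undefined (NaN, flagged) since the t statistic diverges.
    """
    base = np.asarray(baseline, dtype=float)
    fu = np.asarray(followup, dtype=float)
    if base.shape != fu.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(base)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    diff = fu - base
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return PairedTestResult(t=0.0, p=1.0, n=n, mean_change=0.0, degenerate=True)
        return PairedTestResult(t=np.inf * np.sign(diff.mean()), p=np.nan, n=n,
                                mean_change=float(diff.mean()), degenerate=True)
    t, p = sps.ttest_rel(fu, base)
    return PairedTestResult(t=float(t), p=float(p), n=n, mean_change=float(diff.mean()))


def group_rate_contrasts(rates, groups, welch: bool = False) -> pd.DataFrame:
    """All pairwise rate comparisons with Tukey-Kramer familywise p-values.

    Returns a frame with one row per group pair: the signed two-sample t
    statistic (pooled within-group variance over all groups by default;
    Welch by flag) and the Tukey-Kramer adjusted p from the
    studentized-range distribution with q = |t| * sqrt(2).
    """
    r = np.asarray(rates, dtype=float)
    g = pd.Series(groups).astype(str).reset_index(drop=True)
    levels = sorted(g.unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = {lvl: int((g == lvl).sum()) for lvl in levels}
    small = {lvl: n for lvl, n in sizes.items() if n < 2}
    if small:
        raise ValueError(f"groups with < 2 members: {small}")
    N = len(r)
    means = {lvl: r[g == lvl].mean() for lvl in levels}
    if welch:
        dfree = None
    else:
        ssw = sum(((r[g == lvl] - means[lvl]) ** 2).sum() for lvl in levels)
        msw = ssw / (N - k)
        if msw == 0:
            raise ValueError("zero within-group variance")
        dfree = N - k
    rows = []
    for a, b in itertools.combinations(levels, 2):
        ra, rb = r[g == a], r[g == b]
        if welch:
            t, _ = sps.ttest_ind(ra, rb, equal_var=False)
            va, vb = ra.var(ddof=1) / len(ra), rb.var(ddof=1) / len(rb)
            dof = (va + vb) ** 2 / (va ** 2 / (len(ra) - 1) + vb ** 2 / (len(rb) - 1))
        else:
            se = np.sqrt(msw * (1 / len(ra) + 1 / len(rb)))
            t = (means[a] - means[b]) / se
            dof = dfree
        q = abs(float(t)) * np.sqrt(2.0)
        p_adj = float(sps.studentized_range.sf(q, k, dof))
        rows.append({"contrast": f"{a} vs {b}", "tStat": float(t),
                     "p_tukey": min(p_adj, 1.0),
                     "n_a": len(ra), "n_b": len(rb)})
    return pd.DataFrame(rows)
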