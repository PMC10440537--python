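"""Cohort-level statistics for the weekly symptom and spectral endpoints.

Implements the study-shaped analyses: RAW/CFB summary tables, one-sample
and paired t-tests on change-from-baseline, the exact binomial sign test
on binned alpha center frequencies, a two-way mixed (between-group x
within-week) repeated-measures ANOVA from explicit sums of squares,
threshold-exceedance proportions, and Fisher's exact 2x2 comparison.
No multiple-testing correction is applied anywhere, matching the source
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psychometrics import ScoreSeries

__all__ = [
    "TestResult",
    "summarize_cohort",
    "one_sample_t",
    "t_from_summary",
    "paired_t",
    "sign_test_binned",
    "rm_anova",
    "threshold_exceedance",
    "fisher_exact_2x2",
]


@dataclass
class TestResult:
    """A test statistic with degrees of freedom and a two-sided p-value."""

    name: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    flags: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "flags": list(self.flags),
            **{k: v for k, v in self.extras.items()},
        }


def summarize_cohort(
    series: Sequence[ScoreSeries], timepoints: Sequence[int]
) -> pd.DataFrame:
    """Table-1-shaped RAW and CFB summary by timepoint.

    Subjects missing a timepoint are excluded from that row's n.  A row
    with n = 1 reports sd = 0 and is flagged; an empty timepoint is
    omitted (flagged in the ``dropped`` attribute of the frame).
    """
    rows = []
    dropped = []
    for week in timepoints:
        for dtype in ("RAW", "CFB"):
            if dtype == "CFB" and week == 0:
                continue
            vals = []
            for s in series:
                if week not in s.totals:
                    continue
                vals.append(s.at(week) - (s.baseline if dtype == "CFB" else 0))
            if not vals:
                dropped.append((week, dtype))
                continue
            v = np.array(vals, dtype=float)
            rows.append({
                "week": week, "data_type": dtype, "n": v.size,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": float(np.median(v)),
                "min": float(v.min()), "max": float(v.max()),
                "flags": "n=1;sd_undefined" if v.size == 1 else "",
            })
    out = pd.DataFrame(rows)
    out.attrs["dropped"] = dropped
    return out


def t_from_summary(mean: float, sd: float, n: int,
                   name: str = "one-sample t (summary)") -> TestResult:
    """One-sample t-test of H0: mu = 0 from summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("degenerate sample: sd must be > 0")
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(name=name, statistic=float(t), df=df, p=float(min(p, 1.0)))


def one_sample_t(values: Sequence[float], name: str = "one-sample t") -> TestResult:
    """Two-sided one-sample t-test of H0: mean = 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    sd = float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    return t_from_summary(float(v.mean()), sd, int(v.size), name=name)


def paired_t(pre_values: Sequence[float], post_values: Sequence[float],
             name: str = "paired t") -> TestResult:
    """Paired two-sided t-test: one-sample t on post - pre differences."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size != post.size:
        raise ValueError(f"length mismatch: {pre.size} vs {post.size}")
    return one_sample_t(post - pre, name=name)


def sign_test_binned(
    pre_freqs: Sequence[float],
    post_freqs: Sequence[float],
    bin_width: float = 0.5,
    anchor: float = 8.0,
) -> TestResult:
    """Exact binomial sign test on binned paired center frequencies.

    Each pre/post frequency is assigned to a bin of ``bin_width`` Hz
    anchored at ``anchor``; pairs whose bin rose count +, fell count -,
    unchanged are ties and are dropped.  The two-sided p is the exact
    binomial tail with success probability 1/2 on the non-tied count.
    """
    pre = np.asarray(pre_freqs, dtype=float)
    post = np.asarray(post_freqs, dtype=float)
    if pre.size != post.size:
        raise ValueError(f"length mismatch: {pre.size} vs {post.size}")
    pre_bin = np.floor((pre - anchor) / bin_width + 1e-9).astype(int)
    post_bin = np.floor((post - anchor) / bin_width + 1e-9).astype(int)
    n_plus = int(np.sum(post_bin > pre_bin))
    n_minus = int(np.sum(post_bin < pre_bin))
    n = n_plus + n_minus
    if n == 0:
        return TestResult(name="binned sign test", statistic=0.0, df=None,
                          p=1.0, flags=("all_ties",),
                          extras={"n_plus": 0, "n_minus": 0, "n_ties": pre.size})
    p = stats.binomtest(n_plus, n, 0.5, alternative="two-sided").pvalue
    return TestResult(
        name="binned sign test", statistic=float(n_plus), df=None,
        p=float(min(p, 1.0)),
        extras={"n_plus": n_plus, "n_minus": n_minus,
                "n_ties": int(pre.size - n)},
    )


def rm_anova(
    values: np.ndarray,
    group: Sequence[str],
) -> TestResult:
    """Two-way mixed ANOVA (between = group, within = week) from explicit SS.

    ``values`` is a complete subject x week matrix (apply listwise deletion
    first); ``group`` assigns each subject (row) to a group.  Returns the
    between-group effect; the within effects (week, group x week) and the
    full sums-of-squares decomposition are in ``extras``.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("values must be subjects x weeks with >= 2 weeks")
    if np.any(~np.isfinite(y)):
        raise ValueError("matrix must be complete; apply listwise deletion first")
    group = np.asarray(group)
    if group.size != y.shape[0]:
        raise ValueError("group labels must match the number of subjects")
    labels, g_idx = np.unique(group, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    for gi, lab in enumerate(labels):
        if np.sum(g_idx == gi) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")

    n, k = y.shape
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    week_mean = y.mean(axis=0)
    group_mean = np.array([y[g_idx == gi].mean() for gi in range(labels.size)])
    n_per_group = np.array([np.sum(g_idx == gi) for gi in range(labels.size)])

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_mean - grand) ** 2).sum())
    ss_group = float(k * (n_per_group * (group_mean - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_group          # error for group effect
    ss_week = float(n * ((week_mean - grand) ** 2).sum())
    cell_mean = np.vstack([y[g_idx == gi].mean(axis=0) for gi in range(labels.size)])
    ss_cells = float(sum(
        n_per_group[gi] * ((cell_mean[gi] - grand) ** 2).sum()
        for gi in range(labels.size)
    ))
    ss_interaction = ss_cells - ss_group - ss_week
    ss_within_subj = ss_total - ss_between_subj
    ss_error = ss_within_subj - ss_week - ss_interaction

    g = labels.size
    df_group, df_subj = g - 1, n - g
    df_week = k - 1
    df_inter = (g - 1) * (k - 1)
    df_error = (n - g) * (k - 1)

    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj if df_subj else float("nan")
    if ms_subj == 0:
        f_group, p_group = 0.0, 1.0
    else:
        f_group = ms_group / ms_subj
        p_group = float(stats.f.sf(f_group, df_group, df_subj))

    def _within(ss: float, df: int) -> tuple[float, float]:
        ms_e = ss_error / df_error if df_error else float("nan")
        if not df or not df_error or ms_e == 0:
            return 0.0, 1.0
        f = (ss / df) / ms_e
        return float(f), float(stats.f.sf(f, df, df_error))

    f_week, p_week = _within(ss_week, df_week)
    f_inter, p_inter = _within(ss_interaction, df_inter)

    return TestResult(
        name="mixed RM-ANOVA (group effect)",
        statistic=float(f_group), df=(df_group, df_subj), p=float(p_group),
        extras={
            "F_week": f_week, "p_week": p_week,
            "F_interaction": f_inter, "p_interaction": p_inter,
            "ss": {
                "total": ss_total, "group": ss_group,
                "subjects_within_groups": ss_subj_within,
                "week": ss_week, "interaction": ss_interaction,
                "error": ss_error,
            },
        },
    )


def threshold_exceedance(
    cfb_drops: Sequence[float], thresholds: Sequence[float] = (5, 10)
) -> dict[float, float]:
    """Fraction of subjects whose drop strictly exceeds each threshold.

    ``cfb_drops`` are baseline-minus-post values (positive = improvement).
    """
    d = np.asarray(cfb_drops, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one subject")
    return {float(t): float(np.mean(d > t)) for t in thresholds}


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    flags: tuple[str, ...] = ()
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        flags = ("zero_margin",)
        return TestResult(name="Fisher exact 2x2", statistic=float("nan"),
                          df=None, p=1.0, flags=flags)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(name="Fisher exact 2x2", statistic=float(odds), df=None,
                      p=float(min(p, 1.0)), flags=flags)
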