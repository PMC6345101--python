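"""Inferential layer: one-way ANOVA with Tamhane T2 post-hoc per animal,
one-way repeated-measures ANOVA with Bonferroni post-hoc across animals, and
dose-response summaries.  Null hypotheses are rejected at p < 0.05.

Tamhane T2 handles the unequal between-state variances typical of
z'-coherence replicates: each pair gets a Welch t statistic with
Welch-Satterthwaite degrees of freedom and a Sidak-style familywise
adjustment 1 - (1-p)^m over the m pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class StatResult:
    test: str
    F: float
    df: tuple
    p: float
    posthoc: np.ndarray | None = None
    posthoc_method: str = ""
    flags: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def oneway_anova(groups) -> StatResult:
    """Classical one-way ANOVA: F = MS_between / MS_within,
    df = (k-1, N-k).  A fully degenerate input (every value identical) has
    no defined F and is flagged."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        return StatResult(test="oneway_anova", F=np.nan, df=(k - 1, n_total - k),
                          p=np.nan, flags=["degenerate: zero total variance"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.f_oneway(*groups)
    return StatResult(test="oneway_anova", F=float(res.statistic),
                      df=(k - 1, n_total - k), p=float(res.pvalue))


def tamhane_posthoc(groups) -> np.ndarray:
    """Tamhane T2 pairwise adjusted p-value matrix (symmetric, unit
    diagonal).

    Per pair: Welch t with Welch-Satterthwaite df, two-sided p, then
    p_adj = 1 - (1-p)^m over the m = k(k-1)/2 pairs, clipped to 1.  Pairs
    where both groups have zero variance resolve by the exact tie: equal
    means give p_adj = 1, unequal means p_adj = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    m = k * (k - 1) // 2
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            vi, vj = gi.var(ddof=1), gj.var(ddof=1)
            if vi == 0 and vj == 0:
                p = 1.0 if gi.mean() == gj.mean() else 0.0
            else:
                si, sj = vi / len(gi), vj / len(gj)
                t = (gi.mean() - gj.mean()) / np.sqrt(si + sj)
                df = (si + sj) ** 2 / (
                    si ** 2 / (len(gi) - 1) + sj ** 2 / (len(gj) - 1))
                p = 2 * sps.t.sf(abs(t), df)
            p_adj = min(1.0, 1.0 - (1.0 - p) ** m) if p > 0 else 0.0
            out[i, j] = out[j, i] = p_adj
    return out


def rm_anova(matrix) -> StatResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions
    matrix (condition effect with subject blocking).

    F = MS_condition / MS_error with df = (c-1, (c-1)(s-1)) and
    SS_error = SS_total - SS_subject - SS_condition.  No sphericity
    correction is applied by default.  ``extras['df_pooled']`` reports the
    alternative (c-1, N-c) convention seen when replicates are pooled rather
    than blocked.  Bonferroni-adjusted paired t-tests fill ``posthoc``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >=2 subjects and conditions")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")
    s, c = m.shape
    grand = m.mean()
    ss_total = ((m - grand) ** 2).sum()
    ss_subj = c * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_cond = s * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = c - 1
    df_err = (c - 1) * (s - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        F = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
    else:
        F = ms_cond / ms_err
        p = float(sps.f.sf(F, df_cond, df_err))
    n_pairs = c * (c - 1) // 2
    post = np.ones((c, c))
    for i in range(c):
        for j in range(i + 1, c):
            d = m[:, i] - m[:, j]
            if np.ptp(d) == 0:
                praw = 1.0 if d.mean() == 0 else 0.0
            else:
                praw = float(sps.ttest_rel(m[:, i], m[:, j]).pvalue)
            post[i, j] = post[j, i] = min(1.0, praw * n_pairs)
    return StatResult(test="rm_anova", F=float(F), df=(df_cond, df_err),
                      p=float(p), posthoc=post, posthoc_method="bonferroni",
                      extras={"df_pooled": (c - 1, s * c - c)})


def dose_response_table(summaries: dict) -> tuple[pd.DataFrame, StatResult | None]:
    """Mean +/- SE of band z'-coherence per dose plus an across-dose test.

    ``summaries`` maps dose label -> ZCoherenceSummary.  When every dose has
    the same number of window replicates the windows are treated as the
    blocking factor of a repeated-measures ANOVA; otherwise a one-way ANOVA
    across doses is used.  A single dose yields a table with no test.
    """
    rows = []
    reps = []
    for dose, summ in summaries.items():
        rows.append({"dose": dose, "mean_z": summ.mean_z, "se_z": summ.se_z,
                     "n_windows": len(summ.per_window_z)})
        reps.append(np.asarray(summ.per_window_z, dtype=float))
    table = pd.DataFrame(rows)
    if len(rows) < 2:
        return table, None
    if len({len(r) for r in reps}) == 1:
        result = rm_anova(np.column_stack(reps))
    else:
        result = oneway_anova(reps)
    return table, result
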