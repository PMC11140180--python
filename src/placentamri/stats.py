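"""Cohort statistics: within-subject ANOVA, Bonferroni pairwise tests,
paired t, and a Table-style summary with compact letter display.

The design is a complete repeated-measures layout: every animal is
measured in every state (basal, TAD1, TAD2).  The omnibus test is the
standard one-way within-subject ANOVA decomposition

    SS_total = SS_subject + SS_condition + SS_error,
    F = MS_condition / MS_error,  df = (k-1, (k-1)(n-1)),

with no sphericity correction by default (a Greenhouse-Geisser flag is
available).  Pairwise comparisons are paired t-tests with Bonferroni
adjustment p_adj = min(1, m p) over the m state pairs, and groups are
lettered so that states sharing a letter are not significantly
different.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RMAnovaResult",
    "PairedTResult",
    "rm_anova",
    "bonferroni_pairwise",
    "paired_t",
    "compact_letters",
    "summarize_cohort",
    "bin_time_series",
]


@dataclass
class RMAnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    gg_epsilon: float | None = None
    degenerate: bool = False


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def _complete_wide(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pivot the long table to animals x states, dropping incomplete animals."""
    sub = table[table["variable"] == variable] if "variable" in table else table
    wide = sub.pivot_table(
        index="animal_id", columns="state", values="value", aggfunc="mean"
    )
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping incomplete animals for {variable!r}: "
            f"{sorted(incomplete)}",
            stacklevel=3,
        )
        wide = wide.drop(index=incomplete)
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError(
            f"incomplete design for {variable!r}: need >=2 animals with "
            f"all states, have {wide.shape[0]} x {wide.shape[1]}"
        )
    # preserve the state sequence of the input, not alphabetical order
    order = [s for s in sub["state"].unique() if s in wide.columns]
    return wide[order]


def rm_anova(table: pd.DataFrame, variable: str,
             gg_correction: bool = False) -> RMAnovaResult:
    """One-way repeated-measures ANOVA on a long (animal, state, value) table.

    With two conditions, F equals the square of the paired t statistic.
    A zero error sum of squares (e.g. all values identical) is returned
    flagged degenerate with p = NaN rather than a spurious rejection.
    """
    wide = _complete_wide(table, variable)
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_condition = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_condition - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error <= 1e-14 * max(ss_total, 1.0):
        return RMAnovaResult(
            f=math.inf if ss_condition > 0 else 0.0, df1=df1, df2=df2,
            p=float("nan"), ss_condition=ss_condition,
            ss_subject=ss_subject, ss_error=ss_error, degenerate=True,
        )
    f = (ss_condition / df1) / ms_error
    eps = None
    if gg_correction:
        eps = _gg_epsilon(y)
        p = float(sps.f.sf(f, df1 * eps, df2 * eps))
    else:
        p = float(sps.f.sf(f, df1, df2))
    return RMAnovaResult(
        f=float(f), df1=df1, df2=df2, p=p,
        ss_condition=float(ss_condition), ss_subject=float(ss_subject),
        ss_error=float(ss_error), gg_epsilon=eps,
    )


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum()
                     + k**2 * mean_all**2)
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def paired_t(x, y) -> PairedTResult:
    """Paired t-test on two equal-length samples.

    Zero-variance differences are degenerate: t = 0 (p = 1) when the
    constant difference is zero, infinite |t| (p = 0) otherwise, both
    flagged rather than silently returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1D samples with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    scale = max(np.abs(d).max(), np.abs(x).max(), 1.0)
    if sd <= 1e-14 * scale:
        if abs(d.mean()) <= 1e-14 * scale:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        sign = 1.0 if d.mean() > 0 else -1.0
        return PairedTResult(t=sign * math.inf, df=n - 1, p=0.0, degenerate=True)
    res = sps.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def bonferroni_pairwise(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Paired t-test per state pair with Bonferroni adjustment.

    Returns a DataFrame with columns (state_a, state_b, t, df, p_raw,
    p_adj, degenerate); p_adj = min(1, m * p_raw) with m the number of
    pairs (3 for three states).
    """
    wide = _complete_wide(table, variable)
    pairs = list(combinations(wide.columns, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        p_adj = min(1.0, m * res.p) if not math.isnan(res.p) else float("nan")
        rows.append(
            {"state_a": a, "state_b": b, "t": res.t, "df": res.df,
             "p_raw": res.p, "p_adj": p_adj, "degenerate": res.degenerate}
        )
    return pd.DataFrame(rows)


def compact_letters(states, pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display from an adjusted pairwise p matrix.

    Greedy insert-and-absorb on the non-significance graph: states are
    processed in their given sequence; a state joins every existing
    letter group it is not significantly different from all members of,
    and opens a new group when none accepts it.  States sharing a letter
    are not significantly different at ``alpha``.
    """
    states = list(states)
    sig = set()
    for _, r in pairwise.iterrows():
        if not math.isnan(r["p_adj"]) and r["p_adj"] < alpha:
            sig.add(frozenset((r["state_a"], r["state_b"])))

    groups: list[list] = []
    for i, s in enumerate(states):
        placed = False
        for g in groups:
            if all(frozenset((s, other)) not in sig for other in g):
                g.append(s)
                placed = True
        if not placed:
            new = [s]
            # absorb earlier states compatible with the whole new group
            for t in states[:i]:
                if all(frozenset((t, other)) not in sig for other in new):
                    new.append(t)
            groups.append(sorted(new, key=states.index))
    # absorb groups fully contained in another
    groups = [
        g for i, g in enumerate(groups)
        if not any(set(g) < set(h) for j, h in enumerate(groups) if i != j)
    ]
    letters = {s: "" for s in states}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for s in g:
            letters[s] += letter
    return letters


def summarize_cohort(cohort: pd.DataFrame, variables, alpha: float = 0.05,
                     gg_correction: bool = False) -> pd.DataFrame:
    """Table-style cohort report: mean +/- SD per state, F, p, letters.

    ``cohort`` is wide (one row per animal x state, one column per
    variable).  Returns one row per variable with per-state ``mean_*``,
    ``sd_*`` and ``letter_*`` columns plus the omnibus F and p.
    """
    states = list(dict.fromkeys(cohort["state"]))
    rows = []
    for var in variables:
        long = cohort[["animal_id", "state", var]].rename(columns={var: "value"})
        long["variable"] = var
        res = rm_anova(long, var, gg_correction=gg_correction)
        pw = bonferroni_pairwise(long, var)
        letters = compact_letters(states, pw, alpha=alpha)
        row = {"variable": var, "F": res.f, "df1": res.df1, "df2": res.df2,
               "p": res.p, "degenerate": res.degenerate}
        for s in states:
            vals = cohort.loc[cohort["state"] == s, var].astype(float)
            row[f"mean_{s}"] = vals.mean()
            row[f"sd_{s}"] = vals.std(ddof=1)
            row[f"letter_{s}"] = letters[s]
        rows.append(row)
    return pd.DataFrame(rows)


def bin_time_series(times_min, values, bin_width_min: float = 5.0) -> pd.DataFrame:
    """Average a time-resolved trace into consecutive bins (e.g. 5-min MAP).

    Returns (bin_start_min, mean) rows; empty bins are dropped.
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values lengths differ")
    idx = np.floor(t / bin_width_min).astype(int)
    df = pd.DataFrame({"bin": idx, "value": v})
    out = df.groupby("bin")["value"].mean().reset_index()
    out["bin_start_min"] = out.pop("bin") * bin_width_min
    return out[["bin_start_min", "value"]]
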