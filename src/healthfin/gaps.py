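"""Sex-disaggregated outcome gaps and their variation across typologies.

Gaps follow the usual sign conventions: HALE gap = female − male (years;
positive = female longevity advantage) and infant-mortality gap = male −
female (per 1000 live births; positive = male excess mortality). Whether
the gaps differ across financing clusters is tested with classical
equal-variance one-way ANOVA — the singleton US cluster enters as a group
of size one, contributing zero within-group sum of squares — followed by
Tukey–Kramer pairwise comparisons (studentized-range adjusted p-values,
valid for unequal group sizes).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range


@dataclasses.dataclass
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series
    ms_within: float


def compute_gaps(weighted: pd.DataFrame, labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-country sex gaps from a time-weighted outcome table.

    Needs columns hale_female, hale_male, im_male, im_female; returns
    hale_gap (female − male) and im_gap (male − female), with the
    financing cluster attached when ``labels`` is given.
    """
    needed = ["hale_female", "hale_male", "im_male", "im_female"]
    missing = [c for c in needed if c not in weighted.columns]
    if missing:
        raise ValueError(f"missing sex-specific column(s): {missing}")
    out = pd.DataFrame(
        {
            "hale_gap": weighted["hale_female"] - weighted["hale_male"],
            "im_gap": weighted["im_male"] - weighted["im_female"],
        },
        index=weighted.index,
    )
    if labels is not None:
        out["cluster"] = labels.reindex(out.index)
    return out


def oneway_anova(values: pd.Series | np.ndarray, groups: pd.Series | np.ndarray) -> AnovaResult:
    """Equal-variance one-way ANOVA of values across group labels.

    F = MS_between / MS_within with df (g−1, n−g). If every group is
    internally constant (zero within-SS) but means differ, F is infinite
    and p is reported as 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    uniq = np.unique(groups)
    g, n = len(uniq), len(values)
    if g < 2:
        raise ValueError("need at least two groups")
    if n - g < 1:
        raise ValueError("need at least one group with two or more members")

    grand = values.mean()
    means, ss_b, ss_w = {}, 0.0, 0.0
    for lab in uniq:
        sub = values[groups == lab]
        m = sub.mean()
        means[lab] = m
        ss_b += len(sub) * (m - grand) ** 2
        ss_w += ((sub - m) ** 2).sum()

    df_b, df_w = g - 1, n - g
    ms_w = ss_w / df_w
    if ms_w == 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_b / df_b) / ms_w
        p = float(f_dist.sf(f_stat, df_b, df_w))
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        group_means=pd.Series(means, name="mean"),
        ms_within=float(ms_w),
    )


def tukey_hsd(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons after a one-way ANOVA.

    For groups i, j the studentized-range statistic is
    q = |m_i − m_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j)); adjusted p-values
    come from the studentized-range distribution with (g, df_within)
    parameters. Pairs where both groups are singletons are flagged
    untestable (p NaN, no reject decision).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    anova = oneway_anova(values, groups)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(anova.group_means.index)
    g, df_w, ms_w = len(uniq), anova.df_within, anova.ms_within

    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = uniq[i], uniq[j]
            na, nb = (groups == a).sum(), (groups == b).sum()
            diff = anova.group_means[a] - anova.group_means[b]
            untestable = na == 1 and nb == 1
            if untestable or ms_w == 0:
                p = np.nan if untestable else 0.0
            else:
                se = np.sqrt(ms_w / 2.0 * (1.0 / na + 1.0 / nb))
                q = abs(diff) / se if se > 0 else np.inf
                p = float(studentized_range.sf(q, g, df_w))
            rows.append({
                "group_a": a,
                "group_b": b,
                "difference": float(diff),
                "p_adjusted": p,
                "reject": bool(p < alpha) if not np.isnan(p) else False,
                "untestable": bool(untestable),
            })
    return pd.DataFrame(rows)
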