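"""TOPSIS composite performance scores and cluster success rates.

Healthy life expectancy (benefit criterion) and infant mortality (cost
criterion) are min-max normalized to [0, 1] with higher = better, and each
country is scored by its relative closeness to the ideal point (1, 1):

    score = 100 · d⁻ / (d⁺ + d⁻),

where d⁺ and d⁻ are Euclidean distances to the ideal and anti-ideal
points and criteria carry equal weight. A country at maximum HALE and
minimum mortality scores exactly 100. Success is a fixed threshold
(default 70, the top-quartile benchmark); the empirical 75th percentile is
available separately for auditing that constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def normalize_outcomes(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize a (HALE, IM) table to [0, 1], higher = better.

    HALE is a benefit criterion: (x − min)/(max − min). Infant mortality is
    a cost criterion and is reversed: (max − x)/(max − min).
    """
    if outcomes.shape[1] != 2:
        raise ValueError("expected exactly two columns (HALE, infant mortality)")
    if len(outcomes) < 2:
        raise ValueError("need at least two countries")
    hale, im = outcomes.iloc[:, 0].astype(float), outcomes.iloc[:, 1].astype(float)
    for name, col in (("HALE", hale), ("infant mortality", im)):
        if col.max() == col.min():
            raise ValueError(f"degenerate range in {name} column")
    return pd.DataFrame(
        {
            "normalized_hale": (hale - hale.min()) / (hale.max() - hale.min()),
            "normalized_im": (im.max() - im) / (im.max() - im.min()),
        },
        index=outcomes.index,
    )


def topsis_scores(normalized: pd.DataFrame, threshold: float = 70.0) -> pd.DataFrame:
    """Closeness scores, ranks and success flags from a normalized matrix.

    Ranks are by descending score; ties share the best (smallest) rank
    number. Returns columns normalized_hale, normalized_im, d_plus,
    d_minus, score, rank, success.
    """
    M = normalized.to_numpy(dtype=float)
    if M.min() < 0 or M.max() > 1:
        raise ValueError("normalized values must lie in [0, 1]")
    d_plus = np.sqrt(((1.0 - M) ** 2).sum(axis=1))
    d_minus = np.sqrt((M ** 2).sum(axis=1))
    if np.any(d_plus + d_minus == 0):
        raise ValueError("degenerate point: zero distance to both ideals")
    score = 100.0 * d_minus / (d_plus + d_minus)
    out = normalized.copy()
    out["d_plus"] = d_plus
    out["d_minus"] = d_minus
    out["score"] = score
    out["rank"] = rankdata(-score, method="min").astype(int)
    out["success"] = score >= threshold
    return out


def success_rates(
    scores: pd.DataFrame,
    labels: pd.Series,
    threshold: float = 70.0,
) -> pd.DataFrame:
    """Per-cluster member count, mean score, ≥threshold count and rate (1 dp)."""
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        missing = labels[labels.isna()].index.tolist()
        raise ValueError(f"unlabeled countries: {missing}")
    rows = []
    for cluster, idx in scores.groupby(labels).groups.items():
        s = scores.loc[idx, "score"]
        n_success = int((s >= threshold).sum())
        rows.append({
            "cluster": cluster,
            "n": len(s),
            "mean_score": float(s.mean()),
            "n_success": n_success,
            "success_rate": round(100.0 * n_success / len(s), 1),
        })
    return pd.DataFrame(rows).sort_values("cluster", ignore_index=True)


def cross_tabulate(financing: pd.Series, outcome: pd.Series) -> pd.DataFrame:
    """Financing-cluster × outcome-tier contingency table with member lists.

    One row per (financing cluster, outcome tier) cell: count, member
    names, and — per financing cluster — the tier-based success rate, i.e.
    the share of the cluster's members sitting in the best outcome tier
    (tier 1). This is the membership-based notion of success, distinct from
    the TOPSIS-threshold rate of :func:`success_rates`.
    """
    if set(financing.index) != set(outcome.index):
        raise ValueError("financing and outcome assignments cover different countries")
    outcome = outcome.reindex(financing.index)
    best_tier = int(outcome.min())
    rows = []
    for fc in sorted(financing.unique()):
        members = financing[financing == fc].index
        in_best = int((outcome[members] == best_tier).sum())
        tier_rate = round(100.0 * in_best / len(members), 1)
        for tier in sorted(outcome.unique()):
            cell = sorted(m for m in members if outcome[m] == tier)
            rows.append({
                "financing_cluster": fc,
                "outcome_tier": tier,
                "count": len(cell),
                "members": "; ".join(cell),
                "tier_success_rate": tier_rate,
            })
    return pd.DataFrame(rows)


def percentile_threshold(scores: pd.DataFrame | pd.Series, q: float) -> float:
    """q-th percentile of the scores (linear interpolation).

    Audits the fixed success constant against the empirical quartile.
    """
    if not 0 < q <= 100:
        raise ValueError("q must lie in (0, 100]")
    s = scores["score"] if isinstance(scores, pd.DataFrame) else scores
    s = np.asarray(s, dtype=float)
    if s.size < 4:
        raise ValueError("need at least four scores for a quartile threshold")
    return float(np.percentile(s, q))
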