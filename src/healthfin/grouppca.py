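"""Group-wise principal-component reduction of the six spending indicators.

Per-capita USD and %-of-GDP measures of the same financing mechanism are
strongly collinear, so each of the three spending groups (out-of-pocket,
voluntary, compulsory) is reduced to its first principal component.
Indicators are z-standardized first (correlation-matrix PCA) because the
two units are incommensurable; for a standardized 2-column group the PC1
variance explained has the closed form (1 + |r|)/2, where r is the column
correlation. PC1 sign is fixed so the per-capita loading is positive.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .panel import SPENDING_GROUPS


@dataclasses.dataclass
class PCGroupResult:
    """First principal component of one spending group."""

    group: str
    loadings: np.ndarray          # unit 2-vector on (per-capita, %GDP)
    variance_explained: float     # leading eigenvalue / trace, in [0, 1]
    scores: pd.Series             # per-country PC1 score


def standardize(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Z-standardize columns (mean 0, sample sd 1, ddof=1).

    Raises on fewer than two rows or a zero-variance column, naming the
    degenerate indicator.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    sub = table[cols].astype(float)
    if len(sub) < 2:
        raise ValueError("standardization needs at least two rows")
    sd = sub.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (sub - sub.mean()) / sd


def fit_group_pc1(matrix: pd.DataFrame, group: str) -> PCGroupResult:
    """PC1 of a standardized 2-column (per-capita, %GDP) matrix."""
    if matrix.shape[1] != 2:
        raise ValueError("each spending group pairs exactly two indicators")
    if len(matrix) < 3:
        raise ValueError("need at least three countries to fit a component")
    X = matrix.to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    if v[0] < 0:  # sign convention: positive loading on the per-capita column
        v = -v
    return PCGroupResult(
        group=group,
        loadings=v,
        variance_explained=float(evals[-1] / evals.sum()),
        scores=pd.Series(X @ v, index=matrix.index, name=group),
    )


def fit_spending_pcs(weighted: pd.DataFrame) -> dict[str, PCGroupResult]:
    """Standardize the six spending columns and fit PC1 per group."""
    results = {}
    for group, cols in SPENDING_GROUPS.items():
        z = standardize(weighted, list(cols))
        results[group] = fit_group_pc1(z, group)
    return results


def pc_scores(results: dict[str, PCGroupResult]) -> pd.DataFrame:
    """Assemble the country × 3 PC-score matrix (oop, voluntary, compulsory).

    All three groups must cover the same countries in the same order; this
    matrix is the input to the MDS embedding.
    """
    expected = list(SPENDING_GROUPS)
    if list(results) != expected:
        raise ValueError(f"need the three groups {expected}, got {list(results)}")
    base = results[expected[0]].scores.index
    for g in expected[1:]:
        if not results[g].scores.index.equals(base):
            raise ValueError(f"country set/order mismatch in group {g!r}")
    return pd.DataFrame({g: results[g].scores for g in expected})
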