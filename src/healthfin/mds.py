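"""Classical (Torgerson) metric multidimensional scaling and diagnostics.

The country × 3 PC-score matrix is converted to a Euclidean distance
matrix, double-centered (−½·J·D²·J), and eigendecomposed; coordinates are
the top-k eigenvectors scaled by the square roots of their eigenvalues.
Because the scores live in exactly three dimensions, the 3-D embedding
reproduces all pairwise distances to machine precision (stress-1 ≈ 0,
Shepard correlation 1). Fit is reported as

    stress-1 = sqrt( Σ_{i<j} (d_ij − d̂_ij)² / Σ_{i<j} d_ij² )

together with the Shepard pairs (original vs embedded distances) and their
Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr


@dataclasses.dataclass
class EmbeddingResult:
    """A k-dimensional classical MDS configuration with fit diagnostics."""

    countries: list[str]
    coordinates: pd.DataFrame          # country × (V1..Vk), centered columns
    eigenvalues: np.ndarray            # k leading eigenvalues
    stress1: float | None = None
    shepard_r: float | None = None
    shepard_pairs: np.ndarray | None = None  # (n_pairs, 2): original, embedded


@dataclasses.dataclass
class ReferenceDistanceTable:
    """Ranked Euclidean distances from one reference country in MDS space."""

    reference: str
    table: pd.DataFrame  # columns country, distance, rank; sorted ascending


def pairwise_distances(scores: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Symmetric zero-diagonal Euclidean distance matrix of the rows."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    if not np.isfinite(X).all():
        raise ValueError("scores contain non-finite entries")
    return squareform(pdist(X))


def stress1(D: np.ndarray, Dhat: np.ndarray) -> float:
    """Kruskal stress-1 between an original and an embedded distance matrix."""
    D = np.asarray(D, float)
    Dhat = np.asarray(Dhat, float)
    if D.shape != Dhat.shape:
        raise ValueError("distance matrices must have the same shape")
    iu = np.triu_indices_from(D, k=1)
    denom = (D[iu] ** 2).sum()
    if denom == 0:
        raise ValueError("stress-1 undefined: all original distances are zero")
    return float(np.sqrt(((D[iu] - Dhat[iu]) ** 2).sum() / denom))


def classical_mds(
    D: np.ndarray,
    k: int,
    countries: list[str] | None = None,
) -> EmbeddingResult:
    """Torgerson scaling of a distance matrix into k dimensions.

    Columns are ordered by descending eigenvalue; each column's sign is
    fixed so the entry for the alphabetically first country is
    non-negative (all distances are orientation-invariant). If fewer than
    k positive eigenvalues exist, trailing dimensions are zero-padded with
    a warning. Negative eigenvalues (non-Euclidean input) are truncated to
    zero.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("D must be symmetric with zero diagonal")
    if not 1 <= k <= n - 1:
        raise ValueError("k must satisfy 1 <= k <= n-1")
    countries = list(countries) if countries is not None else [str(i) for i in range(n)]

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    top = evals[:k].copy()
    tol = 1e-12 * max(abs(evals[0]), 1.0)
    n_pos = int((top > tol).sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; zero-padding {k - n_pos} "
            "trailing dimension(s)",
            stacklevel=2,
        )
    top[top <= tol] = 0.0
    coords = evecs[:, :k] * np.sqrt(top)

    anchor = int(np.argmin(np.asarray(countries, dtype=object)))
    flip = coords[anchor] < 0
    coords[:, flip] *= -1

    frame = pd.DataFrame(
        coords, index=countries, columns=[f"V{i + 1}" for i in range(k)]
    )
    frame.index.name = "country"
    Dhat = squareform(pdist(coords))
    iu = np.triu_indices(n, k=1)
    pairs = np.column_stack([D[iu], Dhat[iu]])
    r = float(pearsonr(pairs[:, 0], pairs[:, 1]).statistic) if n > 2 else 1.0
    return EmbeddingResult(
        countries=countries,
        coordinates=frame,
        eigenvalues=top,
        stress1=stress1(D, Dhat),
        shepard_r=r,
        shepard_pairs=pairs,
    )


def stress_per_dimension(D: np.ndarray, k_max: int = 5,
                         countries: list[str] | None = None) -> pd.DataFrame:
    """Stress-1 of the classical solution for k = 1..k_max (model inspection)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(1, min(k_max, D.shape[0] - 1) + 1):
            rows.append({"k": k, "stress1": classical_mds(D, k, countries).stress1})
    return pd.DataFrame(rows)


def distances_to_reference(
    embedding: EmbeddingResult | pd.DataFrame, reference: str
) -> ReferenceDistanceTable:
    """Euclidean distances from one country in coordinate space, ranked.

    Accepts an :class:`EmbeddingResult` or a coordinate DataFrame indexed
    by country. The reference appears first with distance 0 and rank 0.
    """
    coords = embedding.coordinates if isinstance(embedding, EmbeddingResult) else embedding
    if len(coords) < 2:
        raise ValueError("need at least two countries to rank distances")
    if reference not in coords.index:
        raise KeyError(f"reference country {reference!r} not in embedding")
    V = coords.to_numpy(dtype=float)
    ref = coords.loc[reference].to_numpy(dtype=float)
    d = np.sqrt(((V - ref) ** 2).sum(axis=1))
    table = (
        pd.DataFrame({"country": coords.index, "distance": d})
        .sort_values(["distance", "country"], kind="mergesort", ignore_index=True)
    )
    table["rank"] = np.arange(len(table))
    return ReferenceDistanceTable(reference=reference, table=table)
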