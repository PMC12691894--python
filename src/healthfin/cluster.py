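"""K-means typologies on MDS coordinates and on standardized outcomes.

Lloyd's algorithm with Forgy initialization (k distinct observations drawn
per start), repeated from ``nstart`` random starts; the lowest-inertia run
wins. Runs that produce an empty cluster are discarded and redrawn.
Cluster ids are relabeled deterministically — by descending size, ties
broken by the centroid's first coordinate — so two runs with the same seed
yield identical label vectors. Validity is reported as the mean silhouette
width (singleton clusters contribute 0) and the between-cluster to total
sum-of-squares ratio.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .panel import RunConfig


@dataclasses.dataclass
class ClusterSolution:
    """A relabeled K-means fit with validity metrics."""

    labels: np.ndarray        # per-observation cluster id in 1..k
    centroids: np.ndarray     # k × dim, row c-1 is cluster c's centroid
    inertia: float            # within-cluster sum of squares
    silhouette: float
    variance_ratio: float     # between-SS / total-SS
    k: int
    seed: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int):
    """One Lloyd run; returns (labels, centers, inertia) or None if a
    cluster empties. Inertia is asserted non-increasing across iterations;
    assignment ties break toward the lower cluster index (argmin)."""
    prev = np.inf
    for _ in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(len(X)), labels].sum())
        assert inertia <= prev + 1e-9 * max(prev, 1.0), "Lloyd inertia increased"
        if np.bincount(labels, minlength=len(centers)).min() == 0:
            return None
        new = np.vstack([X[labels == j].mean(axis=0) for j in range(len(centers))])
        if np.allclose(new, centers):
            break
        centers, prev = new, inertia
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    return labels, centers, float(d2[np.arange(len(X)), labels].sum())


def _relabel(labels: np.ndarray, centers: np.ndarray):
    """Deterministic ids: descending size, ties by centroid first coordinate."""
    sizes = np.bincount(labels, minlength=len(centers))
    order = sorted(range(len(centers)), key=lambda j: (-sizes[j], centers[j, 0]))
    remap = np.empty(len(centers), dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[labels], centers[order]


def kmeans(
    X: np.ndarray | pd.DataFrame,
    k: int,
    nstart: int = 50,
    max_iter: int = 100,
    seed: int = 0,
) -> ClusterSolution:
    """Best-of-``nstart`` Lloyd K-means, deterministic given the seed."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 2 <= k < n:
        raise ValueError("need n > k >= 2")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("k exceeds the number of distinct points")
    rng = np.random.default_rng(seed)

    best = None
    done = 0
    while done < nstart:
        idx = rng.choice(n, size=k, replace=False)  # Forgy: k distinct points
        result = _lloyd(X, X[idx].copy(), max_iter)
        if result is None:
            continue  # empty cluster: discard this start and redraw
        done += 1
        if best is None or result[2] < best[2]:
            best = result

    labels, centers = _relabel(best[0], best[1])
    return ClusterSolution(
        labels=labels,
        centroids=centers,
        inertia=best[2],
        silhouette=silhouette_width(X, labels),
        variance_ratio=variance_ratio(X, labels),
        k=k,
        seed=seed,
    )


def silhouette_width(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singleton clusters contribute 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return float(silhouette_samples(X, labels).mean())


def variance_ratio(X: np.ndarray, labels: np.ndarray) -> float:
    """Between-cluster SS over total SS about the grand centroid."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("variance ratio undefined for a single cluster")
    grand = X.mean(axis=0)
    total = float(((X - grand) ** 2).sum())
    if total == 0:
        raise ValueError("variance ratio undefined: zero total sum of squares")
    between = 0.0
    for c in np.unique(labels):
        sub = X[labels == c]
        between += len(sub) * float(((sub.mean(axis=0) - grand) ** 2).sum())
    return between / total


def choose_k(
    X: np.ndarray | pd.DataFrame,
    k_range: list[int],
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Inertia (elbow curve) and silhouette per k; recommends argmax silhouette.

    The recommendation is stored in ``attrs['recommended_k']``; the elbow
    curve is the ``inertia`` column, emitted for visual inspection.
    """
    config = config or RunConfig()
    rows = []
    for k in k_range:
        sol = kmeans(X, k, config.nstart, config.max_iter, config.seed)
        rows.append({"k": k, "inertia": sol.inertia, "silhouette": sol.silhouette})
    report = pd.DataFrame(rows)
    report.attrs["recommended_k"] = int(report.loc[report["silhouette"].idxmax(), "k"])
    return report


def outcome_clusters(
    outcomes: pd.DataFrame,
    k: int = 3,
    config: RunConfig | None = None,
) -> ClusterSolution:
    """Performance tiers from standardized (HALE, infant mortality) data.

    Columns are z-standardized, then K-means is fit; tiers are renumbered
    by the HALE centroid descending, so tier 1 is the best-performing
    (highest HALE) group regardless of cluster sizes.
    """
    from .grouppca import standardize

    config = config or RunConfig()
    if outcomes.shape[1] != 2:
        raise ValueError("outcome clustering expects exactly (HALE, IM) columns")
    Z = standardize(outcomes).to_numpy()
    sol = kmeans(Z, k, config.nstart, config.max_iter, config.seed)
    order = np.argsort(-sol.centroids[:, 0])  # first column = standardized HALE
    remap = np.empty(k + 1, dtype=int)
    for tier, old in enumerate(order, start=1):
        remap[old + 1] = tier
    return ClusterSolution(
        labels=remap[sol.labels],
        centroids=sol.centroids[order],
        inertia=sol.inertia,
        silhouette=sol.silhouette,
        variance_ratio=sol.variance_ratio,
        k=k,
        seed=sol.seed,
    )


def stability_check(
    X: np.ndarray | pd.DataFrame,
    k: int,
    seeds: list[int],
    nstart: int = 50,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Pairwise ARI of K-means solutions across seeds; reports the minimum.

    With enough restarts on well-separated data every seed reaches the same
    optimum and the minimum pairwise ARI is 1.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    sols = [kmeans(X, k, nstart, max_iter, s) for s in seeds]
    rows = []
    for i in range(len(seeds)):
        for j in range(i + 1, len(seeds)):
            rows.append({
                "seed_a": seeds[i],
                "seed_b": seeds[j],
                "ari": adjusted_rand_score(sols[i].labels, sols[j].labels),
            })
    report = pd.DataFrame(rows)
    report.attrs["min_ari"] = float(report["ari"].min())
    return report
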