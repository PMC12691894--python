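"""End-to-end drivers chaining the pipeline stages.

The financing pipeline runs weighting → group PCA → classical MDS →
K-means on a long panel and returns every intermediate product, so the
λ-sensitivity scan, the synthetic recovery checks and the analysis scripts
all exercise the same code path.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .cluster import ClusterSolution, kmeans, outcome_clusters
from .grouppca import fit_spending_pcs, pc_scores
from .mds import EmbeddingResult, classical_mds, pairwise_distances
from .panel import RunConfig
from .weighting import weight_panel


@dataclasses.dataclass
class PipelineResult:
    """All intermediate products of the financing-typology pipeline."""

    weighted: pd.DataFrame         # country × indicator λ-weighted means
    scores: pd.DataFrame           # country × 3 group PC1 scores
    embedding: EmbeddingResult     # 3-D classical MDS configuration
    solution: ClusterSolution      # financing K-means fit
    labels: pd.Series              # per-country cluster id (1..k)


def financing_pipeline(
    panel: pd.DataFrame,
    lam: float | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Weight a panel, reduce to PC scores, embed, and cluster."""
    config = config or RunConfig()
    lam = config.lam if lam is None else lam
    weighted = weight_panel(panel, lam)
    scores = pc_scores(fit_spending_pcs(weighted))
    D = pairwise_distances(scores)
    embedding = classical_mds(D, k=3, countries=list(scores.index))
    solution = kmeans(
        embedding.coordinates.to_numpy(),
        config.k_financing,
        config.nstart,
        config.max_iter,
        config.seed,
    )
    labels = pd.Series(solution.labels, index=scores.index, name="cluster")
    return PipelineResult(weighted, scores, embedding, solution, labels)


def outcome_pipeline(
    weighted: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[ClusterSolution, pd.Series]:
    """Performance tiers from the weighted total HALE and infant mortality."""
    config = config or RunConfig()
    outcomes = weighted[["hale_total", "im_total"]]
    sol = outcome_clusters(outcomes, config.k_outcome, config)
    return sol, pd.Series(sol.labels, index=outcomes.index, name="tier")
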