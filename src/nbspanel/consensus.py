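"""Consensus clustering over subsampled factorization replicates.

Each replicate draws 80% of the patients without replacement, re-normalizes
their smoothed profiles, factorizes, and records cluster labels.  The
consensus matrix holds, per patient pair, the fraction of co-sampled
replicates in which the pair shared a cluster.  Average-linkage hierarchical
clustering of 1 - consensus gives the final subtypes; the cophenetic
correlation coefficient (ccc) between consensus distances and dendrogram
cophenetic distances measures how block-like — i.e. how stable — the
clustering is (near 1 = clean separation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import BinaryMutationMatrix
from .graph_nmf import NmfConfig, assign_clusters, factorize
from .network_ops import GeneNetwork, KnnGraph
from .propagation import PropagationConfig, propagate, quantile_normalize_columns

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusMatrix",
    "SubtypeAssignment",
    "run_replicates",
    "consensus_matrix",
    "average_linkage_cluster",
    "cophenetic_coefficient",
]


@dataclass
class ConsensusMatrix:
    """Patient x patient co-membership frequencies over replicates."""

    values: np.ndarray
    co_sampled_counts: np.ndarray
    n_replicates: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diagonal(self.values), 1.0):
            raise ValueError("consensus diagonal must be 1")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("consensus entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SubtypeAssignment:
    """Final cluster label per patient at a given K, plus the ccc."""

    labels: np.ndarray
    K: int
    ccc: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.ccc <= 1.0 + 1e-12:
            raise ValueError("ccc must lie in [-1, 1]")


def _replicate_seed(master_seed: int, rep: int) -> int:
    """Deterministic per-replicate seed: child ``rep`` of the master seed."""
    return int(np.random.SeedSequence([master_seed, rep]).generate_state(1)[0] % (2**31))


def run_replicates(
    F0: BinaryMutationMatrix,
    normalized_net: GeneNetwork,
    knn: KnnGraph,
    nmf_cfg: NmfConfig,
    *,
    prop_cfg: PropagationConfig | None = None,
    n_reps: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subsampled smooth-normalize-factorize-assign replicates.

    Propagation is linear and column-wise independent, so the full-cohort
    smoothed matrix is computed once and each replicate re-applies quantile
    normalization to its sampled column subset — mathematically identical
    to propagating the subset, at a fraction of the cost.

    Returns ``[(sampled_column_indices, labels), ...]``.  Per-replicate
    sampling seeds are derived deterministically from ``seed``; the
    factorization is initialized from the master seed itself, so replicate
    diversity comes from patient resampling alone (with ``subsample=1``
    every replicate is identical).
    """
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = F0.n_samples
    n_draw = int(np.floor(subsample * n))
    if n_draw < nmf_cfg.K:
        raise ValueError(
            f"subsample {subsample} draws {n_draw} patients, fewer than K={nmf_cfg.K}"
        )
    smoothed = propagate(F0, normalized_net, prop_cfg or PropagationConfig())

    replicates: list[tuple[np.ndarray, np.ndarray]] = []
    for rep in range(n_reps):
        rep_seed = _replicate_seed(seed, rep)
        rng = np.random.default_rng(rep_seed)
        cols = np.sort(rng.choice(n, size=n_draw, replace=False))
        F = quantile_normalize_columns(smoothed[:, cols]).values
        cfg = NmfConfig(
            K=nmf_cfg.K, lam=nmf_cfg.lam, tol=nmf_cfg.tol,
            rel_tol=nmf_cfg.rel_tol, max_iter=nmf_cfg.max_iter, seed=seed,
        )
        result = factorize(F, knn, cfg)
        labels = assign_clusters(result.H, [F0.samples[c] for c in cols])
        replicates.append((cols, labels))
    return replicates


def consensus_matrix(
    replicates: list[tuple[np.ndarray, np.ndarray]],
    n: int,
) -> ConsensusMatrix:
    """Co-membership frequency over the replicates where a pair co-occurred.

    Entry (i, j) = (#replicates with i, j co-sampled and same label)
    / (#replicates with i, j co-sampled).  The diagonal is 1.  Pairs never
    co-sampled (vanishingly rare at the default 80% x 500) fall back to 0
    with a logged warning count.
    """
    same = np.zeros((n, n))
    both = np.zeros((n, n))
    for cols, labels in replicates:
        indicator = np.zeros(n, bool)
        indicator[cols] = True
        both += np.outer(indicator, indicator)
        for lab in np.unique(labels):
            members = cols[labels == lab]
            sel = np.zeros(n, bool)
            sel[members] = True
            same += np.outer(sel, sel)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(both > 0, same / np.maximum(both, 1), 0.0)
    never = int((np.triu(both, 1) == 0)[np.triu_indices(n, 1)].sum())
    if never:
        logger.warning("consensus_matrix: %d pairs never co-sampled; similarity set to 0", never)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)  # guard tiny float asymmetry
    return ConsensusMatrix(
        values=values, co_sampled_counts=both.astype(int), n_replicates=len(replicates)
    )


def _linkage(C: ConsensusMatrix) -> np.ndarray:
    dist = 1.0 - C.values
    np.fill_diagonal(dist, 0.0)
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


def average_linkage_cluster(C: ConsensusMatrix, K: int) -> np.ndarray:
    """Cut the average-linkage tree of 1 - consensus into exactly K clusters.

    Labels are 1-based, renumbered by first appearance for determinism.
    """
    n = C.n
    if K > n:
        raise ValueError(f"K={K} exceeds the number of patients ({n})")
    if K == 1:
        return np.ones(n, dtype=int)
    raw = hierarchy.cut_tree(_linkage(C), n_clusters=K).ravel()
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels[i] = relabel[r]
    return labels


def cophenetic_coefficient(C: ConsensusMatrix) -> float:
    """Pearson correlation between consensus distances (1 - similarity)
    and the cophenetic distances of the average-linkage tree."""
    if C.n < 3:
        raise ValueError("need at least 3 patients for a cophenetic coefficient")
    dist = 1.0 - C.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.ptp(condensed) == 0:
        raise ValueError("all pairwise consensus distances are equal; ccc undefined")
    ccc, _ = hierarchy.cophenet(_linkage(C), condensed)
    return float(ccc)
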