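"""Network propagation of mutation profiles and quantile normalization.

Sparse binary mutation profiles are smoothed over the gene network by the
random-walk-with-restart style iteration

    F_{t+1} = a * A * F_t + (1 - a) * F_0

where ``a`` (default 0.7) is the fraction of signal that keeps diffusing and
``A`` is the degree-normalized adjacency.  The iteration converges to
``(1 - a) (I - aA)^(-1) F_0``; we iterate until the max-abs change between
successive iterates drops below ``tol`` (default 0.001).  Quantile
normalization across patients is applied afterwards so every patient's
smoothed profile follows the same distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import BinaryMutationMatrix
from .network_ops import GeneNetwork

__all__ = [
    "PropagationConfig",
    "SmoothedProfileMatrix",
    "propagate",
    "quantile_normalize_columns",
]


@dataclass
class PropagationConfig:
    """Propagation parameters: retention weight ``alpha`` in [0, 1),
    convergence threshold ``tol`` and an iteration safety cap."""

    alpha: float = 0.7
    tol: float = 1e-3
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class SmoothedProfileMatrix:
    """Non-negative smoothed gene x patient matrix after normalization."""

    values: np.ndarray
    genes: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("smoothed profiles must be non-negative")


def propagate(
    F0: BinaryMutationMatrix | np.ndarray,
    A: GeneNetwork | np.ndarray,
    cfg: PropagationConfig | None = None,
) -> np.ndarray:
    """Iterate ``F_{t+1} = a A F_t + (1-a) F_0`` to convergence.

    ``A`` must be normalized (spectral radius below ``1/alpha``) so the
    iteration converges; the gene order of ``A`` must match ``F0``.
    Returns the smoothed m x n matrix (not yet quantile-normalized).
    """
    cfg = cfg or PropagationConfig()
    F0m = F0.values.astype(float) if isinstance(F0, BinaryMutationMatrix) else np.asarray(F0, float)
    Am = A.weights if isinstance(A, GeneNetwork) else np.asarray(A, float)
    if Am.shape[0] != F0m.shape[0]:
        raise ValueError(f"adjacency dimension {Am.shape[0]} != gene count {F0m.shape[0]}")
    if cfg.alpha == 0:
        return F0m.copy()
    F = F0m.copy()
    restart = (1 - cfg.alpha) * F0m
    for _ in range(cfg.max_iter):
        F_next = cfg.alpha * (Am @ F) + restart
        delta = np.abs(F_next - F).max()
        F = F_next
        if delta < cfg.tol:
            return F
    raise RuntimeError(
        f"propagation did not converge within {cfg.max_iter} iterations "
        f"(last max-abs change {delta:.3g} >= tol {cfg.tol:.3g})"
    )


def quantile_normalize_columns(
    F: np.ndarray,
    genes: list[str] | None = None,
    samples: list[str] | None = None,
) -> SmoothedProfileMatrix:
    """Force every column (patient) onto the same value distribution.

    The reference distribution is the mean across columns of the
    within-column sorted values; each column's entries are replaced by the
    reference value at their within-column rank.  Ties — pervasive here
    because profiles originate from binary matrices — receive the mean of
    the reference values over the tied rank range, so the map is
    permutation-equivariant within a column.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 1:
        raise ValueError("need an m x n matrix with n >= 1")
    m, n = F.shape
    order = np.argsort(F, axis=0, kind="stable")
    reference = np.take_along_axis(F, order, axis=0).mean(axis=1)

    out = np.empty_like(F)
    for j in range(n):
        col = F[:, j]
        ranked = np.empty(m)
        ranked[order[:, j]] = reference
        # average reference values over runs of tied column values
        sorted_col = col[order[:, j]]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(order[:, j], boundaries)
        refs = np.split(reference, boundaries)
        for idx, ref in zip(groups, refs):
            ranked[idx] = ref.mean()
        out[:, j] = ranked
    return SmoothedProfileMatrix(values=out, genes=genes or [], samples=samples or [])
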