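"""Network-regularized non-negative matrix factorization.

Minimizes, over non-negative W (m x K metagenes) and H (K x n loadings),

    ||F - W H||_F^2  +  lambda * trace(W^T L W)

where L = D - C is the Laplacian of the k-nearest-neighbor gene graph.  The
penalty makes each metagene vary smoothly over the interaction network:
neighboring genes are pushed to similar basis weights.  Solved by the
multiplicative update rules for graph-regularized NMF,

    H <- H * (W^T F) / (W^T W H)
    W <- W * (F H^T + lambda C W) / (W H H^T + lambda D W)

which keep factors non-negative and never increase the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_ops import GraphLaplacian, KnnGraph

__all__ = ["NmfConfig", "FactorizationResult", "objective", "factorize", "assign_clusters"]

_EPS = np.finfo(float).eps


@dataclass
class NmfConfig:
    """Factorization parameters.

    K is the rank (number of subtypes), lam the network-regularization
    weight (default 200), tol the absolute objective-decrease threshold
    (default 0.1, with a relative fallback of 1e-6 for large objectives).
    """

    K: int = 4
    lam: float = 200.0
    tol: float = 0.1
    rel_tol: float = 1e-6
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FactorizationResult:
    """Non-negative basis W (metagenes), loadings H, and objective trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def K(self) -> int:
        return self.W.shape[1]


def objective(
    F: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    L: GraphLaplacian | np.ndarray | None = None,
    lam: float = 0.0,
) -> float:
    """Squared Frobenius reconstruction error plus lam * tr(W^T L W)."""
    F = np.asarray(F, float)
    if W.shape[0] != F.shape[0] or H.shape[1] != F.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: F {F.shape}, W {W.shape}, H {H.shape}"
        )
    value = float(np.linalg.norm(F - W @ H, "fro") ** 2)
    if lam != 0.0 and L is not None:
        Lm = L.L if isinstance(L, GraphLaplacian) else np.asarray(L, float)
        value += lam * float(np.trace(W.T @ Lm @ W))
    return value


def factorize(
    F: np.ndarray,
    graph: KnnGraph | None,
    cfg: NmfConfig,
) -> FactorizationResult:
    """Run the multiplicative-update solver to convergence.

    ``graph`` supplies the k-NN connectivity C (and its degree matrix D)
    used in the W update; pass None for plain NMF (equivalent to lam=0).
    Initialization is i.i.d. uniform(0,1) scaled by mean(F)/K, controlled
    by ``cfg.seed``; identical seeds give identical traces.
    """
    F = np.asarray(F, dtype=float)
    if (F < 0).any():
        raise ValueError("F must be non-negative")
    m, n = F.shape
    K = cfg.K
    if graph is not None and cfg.lam > 0:
        C = graph.connectivity
        D = np.diag(C.sum(axis=1))
        L = D - C
    else:
        C = D = L = None

    rng = np.random.default_rng(cfg.seed)
    scale = max(F.mean() / K, _EPS)
    W = rng.uniform(0.0, 1.0, size=(m, K)) * scale
    H = rng.uniform(0.0, 1.0, size=(K, n)) * scale

    trace: list[float] = [objective(F, W, H, L, cfg.lam if L is not None else 0.0)]
    converged = False
    for _ in range(cfg.max_iter):
        # H update: standard NMF multiplicative rule
        H *= (W.T @ F) / np.maximum(W.T @ W @ H, _EPS)
        # W update: graph-regularized rule
        numer = F @ H.T
        denom = W @ (H @ H.T)
        if L is not None:
            numer = numer + cfg.lam * (C @ W)
            denom = denom + cfg.lam * (D @ W)
        W *= numer / np.maximum(denom, _EPS)

        obj = objective(F, W, H, L, cfg.lam if L is not None else 0.0)
        prev = trace[-1]
        trace.append(obj)
        decrease = prev - obj
        if abs(decrease) < cfg.tol or (prev > 0 and abs(decrease) / prev < cfg.rel_tol):
            converged = True
            break
    return FactorizationResult(W=W, H=H, objective_trace=trace, converged=converged)


def assign_clusters(H: np.ndarray, samples: list[str] | None = None) -> np.ndarray:
    """Assign each sample to the metagene with the largest loading.

    Labels are 1-based (1..K); ties go to the lowest metagene index.
    An all-zero loading column is ambiguous and raises, naming the sample.
    """
    H = np.asarray(H, float)
    if (H < 0).any():
        raise ValueError("H must be non-negative")
    zero = np.flatnonzero(~H.any(axis=0))
    if zero.size:
        name = samples[zero[0]] if samples else f"column {zero[0]}"
        raise ValueError(f"sample {name} has an all-zero loading vector")
    return H.argmax(axis=0) + 1
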