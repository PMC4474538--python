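"""Gene interaction network: adjacency, k-NN connectivity, graph Laplacian.

The interaction network plays two roles.  Its (degree-normalized) adjacency
drives label propagation of mutation profiles; its k-nearest-neighbor
connectivity graph supplies the Laplacian ``L = D - C`` that regularizes the
matrix factorization so metagenes vary smoothly over the network.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "KnnGraph",
    "GraphLaplacian",
    "read_network",
    "top_fraction_edges",
    "normalize_adjacency",
    "knn_graph",
    "laplacian",
]


@dataclass
class GeneNetwork:
    """Weighted undirected gene graph as a symmetric non-negative matrix."""

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        m = len(self.genes)
        if self.weights.shape != (m, m):
            raise ValueError(f"weight matrix shape {self.weights.shape} != ({m}, {m})")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weight matrix must be symmetric")
        if (self.weights < 0).any():
            raise ValueError("edge weights must be non-negative")
        if np.diagonal(self.weights).any():
            raise ValueError("self-loops are not allowed (non-zero diagonal)")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def subset(self, genes: list[str]) -> "GeneNetwork":
        """Induced subgraph on ``genes`` (which must all be present),
        in the given order."""
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = np.array([idx[g] for g in genes])
        return GeneNetwork(genes=list(genes), weights=self.weights[np.ix_(rows, rows)])

    def to_edge_list(self) -> list[tuple[str, str, float]]:
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        return [(self.genes[i], self.genes[j], float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g1, g2, w in self.to_edge_list():
                fh.write(f"{g1}\t{g2}\t{w:.6g}\n")


@dataclass
class KnnGraph:
    """Symmetric k-nearest-neighbor connectivity matrix (zero diagonal)."""

    connectivity: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.connectivity = np.asarray(self.connectivity, dtype=float)
        if not np.allclose(self.connectivity, self.connectivity.T):
            raise ValueError("connectivity must be symmetric")
        if np.diagonal(self.connectivity).any():
            raise ValueError("connectivity diagonal must be zero")


@dataclass
class GraphLaplacian:
    """Graph Laplacian ``L = D - C``: symmetric, rows summing to zero, PSD."""

    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if not np.allclose(self.L, self.L.T):
            raise ValueError("Laplacian must be symmetric")
        if not np.allclose(self.L.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("Laplacian rows must sum to zero")


def read_network(path: str | Path) -> GeneNetwork:
    """Read a 3-column edge list (gene, gene, weight; ``#`` comments).

    Duplicated directed edges are symmetrized by taking the maximum weight;
    self-loops are dropped with a logged count.
    """
    genes: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[int, int, float]] = []
    n_self = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'gene1 gene2 weight', got {raw!r}")
        g1, g2 = parts[0].strip().upper(), parts[1].strip().upper()
        try:
            w = float(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric edge weight {parts[2]!r}") from None
        for g in (g1, g2):
            if g not in index:
                index[g] = len(genes)
                genes.append(g)
        if g1 == g2:
            n_self += 1
            continue
        edges.append((index[g1], index[g2], w))
    if n_self:
        logger.info("read_network: dropped %d self-loops", n_self)
    m = len(genes)
    weights = np.zeros((m, m))
    for i, j, w in edges:
        weights[i, j] = max(weights[i, j], w)
        weights[j, i] = max(weights[j, i], w)
    return GeneNetwork(genes=genes, weights=weights)


def top_fraction_edges(net: GeneNetwork, fraction: float) -> GeneNetwork:
    """Keep the ``ceil(fraction * E)`` highest-weight edges.

    All edges tied with the cutoff weight are kept, so the result can
    slightly exceed the nominal count.  Isolated genes stay in the gene
    list (they become zero rows).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    upper = np.triu(net.weights, 1)
    edge_weights = upper[upper > 0]
    if edge_weights.size == 0:
        raise ValueError("network has no edges")
    if fraction == 1.0:
        return GeneNetwork(genes=list(net.genes), weights=net.weights.copy())
    n_keep = math.ceil(fraction * edge_weights.size)
    cutoff = np.sort(edge_weights)[::-1][n_keep - 1]
    kept = np.where(net.weights >= cutoff, net.weights, 0.0)
    return GeneNetwork(genes=list(net.genes), weights=kept)


def normalize_adjacency(net: GeneNetwork, scheme: str = "symmetric-degree") -> GeneNetwork:
    """Normalize the adjacency so the propagation iteration converges.

    ``symmetric-degree`` (default) returns ``D^(-1/2) A D^(-1/2)`` whose
    spectral radius is at most 1; ``row-stochastic`` returns ``D^(-1) A``;
    ``none`` returns the adjacency unchanged.  Isolated genes get zero rows.
    """
    if scheme == "none":
        return GeneNetwork(genes=list(net.genes), weights=net.weights.copy())
    deg = net.weights.sum(axis=1)
    with np.errstate(divide="ignore"):
        if scheme == "symmetric-degree":
            d = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
            normalized = d[:, None] * net.weights * d[None, :]
        elif scheme == "row-stochastic":
            d = np.where(deg > 0, 1.0 / deg, 0.0)
            normalized = d[:, None] * net.weights
            # symmetrize to keep the GeneNetwork contract; average of the
            # two directed normalizations
            normalized = 0.5 * (normalized + normalized.T)
        else:
            raise ValueError(f"unknown normalization scheme {scheme!r}")
    return GeneNetwork(genes=list(net.genes), weights=normalized)


def knn_graph(net: GeneNetwork, k: int, *, binary: bool = True) -> KnnGraph:
    """Build the union k-nearest-neighbor graph.

    Genes i and j are connected if i is among the k highest-weight
    neighbors of j or vice versa.  Ties at the k-th weight are broken by
    lexicographic gene symbol, making the result deterministic.  Genes with
    fewer than k neighbors use all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = net.n_genes
    order = np.argsort(net.genes)  # lexicographic rank per index
    lexrank = np.empty(m, dtype=int)
    lexrank[order] = np.arange(m)
    conn = np.zeros((m, m))
    for i in range(m):
        w = net.weights[i]
        nbrs = np.flatnonzero(w > 0)
        if nbrs.size == 0:
            continue
        # sort by descending weight, then lexicographic symbol
        sel = nbrs[np.lexsort((lexrank[nbrs], -w[nbrs]))][:k]
        conn[i, sel] = 1.0 if binary else w[sel]
        conn[sel, i] = np.maximum(conn[sel, i], conn[i, sel])
    conn = np.maximum(conn, conn.T)
    if not binary:
        # carry the original weight on every kept edge
        conn = np.where(conn > 0, net.weights, 0.0)
    return KnnGraph(connectivity=conn, k=k)


def laplacian(graph: KnnGraph) -> GraphLaplacian:
    """``L = D - C`` with D the diagonal of row sums of the connectivity."""
    C = graph.connectivity
    return GraphLaplacian(L=np.diag(C.sum(axis=1)) - C)
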