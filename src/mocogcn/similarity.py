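"""Per-view weighted sample-similarity graphs.

Nodes are samples; edge weights are cosine similarities retained above a
threshold epsilon. Epsilon is not set directly: the edge-density parameter
``k`` asks for an average of at least ``k`` retained edges per node, and
epsilon is the *largest* off-diagonal similarity achieving that, so the
graph is as sparse as ``k`` allows. ``k = 1`` keeps no edges (every node
already "retains" its self-similarity in the average), so graph
convolution degenerates to a plain per-sample neural network.

The propagation operator is the symmetric renormalization
``A_hat = D^{-1/2} (A + I) D^{-1/2}`` with D the degree matrix of
``A + I``; including the self-loop in the degree keeps the operator
defined on isolated nodes and its spectrum within [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import OmicsView


@dataclass
class SimilarityGraph:
    """Cosine similarity matrix with its thresholded adjacency and operator."""

    S: np.ndarray
    epsilon: float
    k: float
    A: np.ndarray
    A_hat: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.A, 1)))


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity ``S_ij = <x_i, x_j> / (|x_i| |x_j|)``.

    Raises if any sample vector is all-zero (its direction, and hence its
    similarity to anything, is undefined).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"sample at row {zero[0]} is all-zero; cosine similarity undefined")
    S = (X / norms[:, None]) @ (X / norms[:, None]).T
    S = np.clip((S + S.T) / 2.0, -1.0, 1.0)  # symmetrize, tame rounding
    np.fill_diagonal(S, 1.0)
    return S


def threshold_from_k(S: np.ndarray, k: float) -> float:
    """Largest threshold retaining on average at least ``k`` edges per node.

    Retention counts off-diagonal entries with ``S_ij >= epsilon``; ties at
    epsilon are all kept. ``k = n - 1`` yields the complete graph. A
    descending sort over the off-diagonal values makes the search exact
    and deterministic.

    ``k = 1`` is the degenerate setting: every node keeps only itself, so
    the threshold is placed just above the largest off-diagonal similarity
    and the graph has no edges (graph convolution then reduces to a plain
    neural network).
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1] = [1, {n - 1}], got {k}")
    off = S[~np.eye(n, dtype=bool)]  # each undirected pair twice: per-node counting
    if k == 1:
        return float(np.nextafter(off.max(), np.inf))
    vals = np.sort(off)[::-1]
    # epsilon = vals[m-1] retains the top m entries (plus ties); need m/n >= k
    m = int(np.ceil(k * n - 1e-9))
    return float(vals[m - 1])


def build_adjacency(S: np.ndarray, epsilon: float) -> np.ndarray:
    """Weighted adjacency: keep ``S_ij`` where ``S_ij >= epsilon``, zero diagonal."""
    S = np.asarray(S, dtype=float)
    A = np.where(S >= epsilon, S, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric renormalized operator ``D^{-1/2} (A + I) D^{-1/2}``."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    AI = A + np.eye(A.shape[0])
    d = AI.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return AI * inv_sqrt[:, None] * inv_sqrt[None, :]


def build_graph(view: OmicsView, k: float, z_score: bool = False) -> SimilarityGraph:
    """End-to-end graph construction for one view.

    ``z_score`` optionally standardizes each feature before cosine
    similarity (off by default: species views are used as loaded relative
    abundances, exposome views as raw 0/1).
    """
    X = view.X
    if z_score:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    S = cosine_similarity_matrix(X)
    eps = threshold_from_k(S, k)
    A = build_adjacency(S, eps)
    return SimilarityGraph(S=S, epsilon=eps, k=k, A=A, A_hat=normalize_adjacency(A))


def write_edge_list(graph: SimilarityGraph, sample_ids: list[str], path: str | Path) -> None:
    """Export the adjacency as an edge-list TSV (node_i, node_j, weight)."""
    with open(path, "w") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        n = graph.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if graph.A[i, j] != 0:
                    fh.write(f"{sample_ids[i]}\t{sample_ids[j]}\t{graph.A[i, j]:.10g}\n")
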