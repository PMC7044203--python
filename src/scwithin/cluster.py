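"""Embedding and community detection: PCA -> t-SNE -> kNN graph -> Louvain.

The chain reproduces a common early-droplet-era workflow: normalized
expression is reduced by PCA (per-gene unit-variance standardization
first), embedded in 2-D with t-SNE (perplexity 20, 3000 iterations by
default), the embedding's Euclidean distances are converted into a
symmetric k-nearest-neighbour graph, and communities are found by
multi-level modularity optimization (Louvain).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

__all__ = ["Embedding", "ClusterLabels", "embed", "build_graph", "louvain"]


@dataclass
class Embedding:
    """2-D cell coordinates plus the parameters that produced them."""

    coords: np.ndarray          # cells x 2
    perplexity: float
    n_iter: int
    seed: int


@dataclass
class ClusterLabels:
    """Per-cell community ids (contiguous from 1, largest first)."""

    labels: np.ndarray
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def embed(
    X,
    n_pcs: int = 30,
    perplexity: float = 20.0,
    n_iter: int = 3000,
    seed: int = 0,
) -> Embedding:
    """PCA then t-SNE on a cells x genes matrix.

    Deterministic for a fixed ``seed``.  ``n_pcs`` must be below both
    dimensions and the perplexity must satisfy the t-SNE feasibility bound
    ``perplexity < (cells - 1) / 3``.
    """
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    n_cells, n_genes = X.shape
    if perplexity >= (n_cells - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} infeasible for {n_cells} cells "
            f"(needs perplexity < {(n_cells - 1) / 3:.1f})"
        )
    n_pcs = min(n_pcs, n_cells - 1, n_genes)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(
        StandardScaler().fit_transform(X)
    )
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
        learning_rate="auto",
    ).fit_transform(pcs)
    if not np.isfinite(coords).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return Embedding(coords=np.asarray(coords, dtype=np.float64),
                     perplexity=perplexity, n_iter=n_iter, seed=seed)


def build_graph(emb: Embedding | np.ndarray, k: int = 60) -> igraph.Graph:
    """Symmetric kNN graph on Euclidean distances in the embedding.

    An edge is present iff either endpoint lists the other among its ``k``
    nearest neighbours (union symmetrization).
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb)
    n = coords.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def louvain(graph: igraph.Graph, seed: int = 0) -> ClusterLabels:
    """Multi-level modularity optimization (Louvain) on an undirected graph.

    Deterministic for a fixed seed and node order.  Cluster ids are
    relabeled by decreasing size, starting at 1; the reported modularity is
    the Newman-Girvan modularity of the returned partition.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    igraph.set_random_number_generator(random.Random(seed))
    try:
        part = graph.community_multilevel()
    finally:
        igraph.set_random_number_generator(random)
    membership = np.asarray(part.membership)
    order = np.argsort([-np.sum(membership == c) for c in range(membership.max() + 1)],
                       kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([relabel[int(m)] for m in membership])
    mod = graph.modularity(membership)
    return ClusterLabels(labels=labels, modularity=float(mod))
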