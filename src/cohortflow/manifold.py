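"""Sample embedding, fuzzy-simplicial connectivity graph and state assignment.

Samples are embedded by PCA on the (optionally log1p-transformed) normalized
expression matrix. The connectivity graph is the weighted kNN graph of the
UMAP fuzzy-simplicial-set construction: per-sample exponential memberships
calibrated so each sample's total membership is log2(k), then symmetrized by
the probabilistic t-conorm. Disease states are Leiden communities of that
graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from cohortflow.data_io import ExpressionMatrix

logger = logging.getLogger(__name__)

SMOOTH_KNN_ITERATIONS = 64
SMOOTH_KNN_TOLERANCE = 1e-5


@dataclass
class Embedding:
    """PCA scores for the samples (rows align 1:1 with sample_ids)."""

    coords: np.ndarray
    sample_ids: list[str]
    explained_variance: np.ndarray

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class ConnectivityGraph:
    """Undirected weighted graph over samples; weights in (0, 1]."""

    nodes: list[str]
    edges: dict[tuple[int, int], float]  # keys (i, j) with i < j, node indices
    n_neighbors: int

    def edge_list(self) -> list[tuple[str, str, float]]:
        return [(self.nodes[i], self.nodes[j], w) for (i, j), w in sorted(self.edges.items())]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (i, j), w in self.edges.items():
            g.add_edge(self.nodes[i], self.nodes[j], weight=w)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in self.edge_list():
                fh.write(f"{u}\t{v}\t{w:.10g}\n")


@dataclass
class StateAssignment:
    """Cluster (disease-state) label per sample; labels contiguous from 0."""

    labels: dict[str, int]
    n_states: int
    resolution: float

    def as_array(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[s] for s in sample_ids], dtype=int)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tstate\n")
            for sid, st in self.labels.items():
                fh.write(f"{sid}\t{st}\n")


def pca_embed(
    m: ExpressionMatrix,
    d: int = 50,
    log_transform: bool = True,
    seed: int = 0,
) -> Embedding:
    """Embed samples by the top-d principal components.

    Samples are observations, genes features; features are centered (and
    log1p-transformed first when ``log_transform``). The sign convention is
    fixed so each component's largest-magnitude gene loading is positive,
    making the embedding deterministic across runs and BLAS builds.
    """
    if d < 2:
        raise ValueError("d must be >= 2")
    x = m.values.T  # samples x genes
    if log_transform:
        x = np.log1p(x)
    max_rank = int(min(x.shape[0] - 1, x.shape[1]))
    if d > max_rank:
        warnings.warn(
            f"requested d={d} exceeds max rank {max_rank}; reducing", stacklevel=2
        )
        d = max_rank
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(d):
        comp = pca.components_[k]
        if comp[np.argmax(np.abs(comp))] < 0:
            scores[:, k] *= -1
    return Embedding(
        coords=scores,
        sample_ids=list(m.sample_ids),
        explained_variance=pca.explained_variance_.copy(),
    )


def smooth_knn_calibrate(knn_dists: np.ndarray, n_neighbors: int) -> tuple[float, float]:
    """Find (rho, sigma) for one sample from its sorted kNN distances.

    rho is the distance to the nearest neighbor. sigma solves
    ``sum_j exp(-max(0, d_j - rho) / sigma) = log2(k)`` by bisection
    (64 iterations, tolerance 1e-5), the standard smooth-kNN calibration
    of the UMAP fuzzy-set construction.
    """
    rho = float(knn_dists[0])
    target = np.log2(n_neighbors)
    shifted = np.maximum(knn_dists - rho, 0.0)

    def total(sigma: float) -> float:
        return float(np.exp(-shifted / sigma).sum())

    lo, hi = 0.0, 1.0
    mid = 1.0
    # grow hi until the membership sum reaches the target (sum increases with sigma)
    while total(hi) < target and hi < 1e12:
        hi *= 2.0
    for _ in range(SMOOTH_KNN_ITERATIONS):
        mid = 0.5 * (lo + hi)
        s = total(mid)
        if abs(s - target) < SMOOTH_KNN_TOLERANCE:
            break
        if s > target:
            hi = mid
        else:
            lo = mid
    return rho, max(mid, 1e-12)


def fuzzy_graph(e: Embedding, n_neighbors: int, seed: int = 0) -> ConnectivityGraph:
    """Fuzzy simplicial set over the embedding: exact Euclidean kNN,
    locally calibrated exponential memberships, probabilistic-union
    symmetrization ``W = A + A' - A o A'``.

    ``seed`` is accepted for interface symmetry; the construction is exact
    and deterministic.
    """
    n = e.coords.shape[0]
    if not 2 <= n_neighbors < n:
        raise ValueError(f"need 2 <= n_neighbors < n_samples, got {n_neighbors} vs {n}")
    dmat = cdist(e.coords, e.coords)
    directed = np.zeros((n, n))
    for u in range(n):
        order = np.argsort(dmat[u], kind="stable")
        nbrs = [v for v in order if v != u][:n_neighbors]
        dists = dmat[u, nbrs]
        rho, sigma = smooth_knn_calibrate(dists, n_neighbors)
        directed[u, nbrs] = np.exp(-np.maximum(dists - rho, 0.0) / sigma)
    sym = directed + directed.T - directed * directed.T
    edges: dict[tuple[int, int], float] = {}
    for i, j in zip(*np.nonzero(np.triu(sym, k=1))):
        edges[(int(i), int(j))] = float(sym[i, j])
    return ConnectivityGraph(nodes=list(e.sample_ids), edges=edges, n_neighbors=n_neighbors)


NEIGHBOR_LADDER = (15, 20, 25, 30, 40, 50, 60)


def select_n_neighbors(
    e: Embedding, ladder: tuple[int, ...] = NEIGHBOR_LADDER
) -> tuple[int, ConnectivityGraph]:
    """Smallest neighbor count from ``ladder`` whose fuzzy graph is
    connected (falling back to the largest feasible value).

    Too few neighbors leave the graph in disconnected islands, so no flow
    can route between them; too many blur the community structure. Scanning
    a small ladder automates the per-dataset neighbor tuning the method
    needs.
    """
    import networkx as nx

    n = e.coords.shape[0]
    feasible = [k for k in ladder if k < n]
    if not feasible:
        raise ValueError("embedding has too few samples for any ladder value")
    graph = None
    for k in feasible:
        graph = fuzzy_graph(e, k)
        if nx.is_connected(graph.to_networkx()):
            logger.info("auto-selected n_neighbors=%d (graph connected)", k)
            return k, graph
    logger.warning(
        "connectivity graph disconnected even at n_neighbors=%d", feasible[-1]
    )
    return feasible[-1], graph


def leiden_states(
    g: ConnectivityGraph, resolution: float = 1.0, seed: int = 0
) -> StateAssignment:
    """Assign disease states by Leiden modularity optimization on the
    weighted connectivity graph. Deterministic given ``seed``; labels are
    re-indexed to be contiguous from 0."""
    import igraph as ig
    import leidenalg

    if not g.nodes:
        raise ValueError("empty connectivity graph")
    pairs = sorted(g.edges)
    graph = ig.Graph(
        n=len(g.nodes), edges=pairs, edge_attrs={"weight": [g.edges[p] for p in pairs]}
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    raw = np.array(part.membership)
    # contiguous relabel (leidenalg already orders by size, keep its order)
    uniq = {lab: k for k, lab in enumerate(dict.fromkeys(raw.tolist()))}
    labels = {sid: uniq[int(lab)] for sid, lab in zip(g.nodes, raw)}
    n_states = len(uniq)
    logger.info("Leiden found %d states at resolution %g", n_states, resolution)
    return StateAssignment(labels=labels, n_states=n_states, resolution=resolution)
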