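import numpy as np
import pytest

from cohortflow.data_io import ExpressionMatrix, SampleMeta
from cohortflow.flow_core import FlowGraph


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_counts(rng, n_genes=50, n_samples=8, mean=60.0) -> ExpressionMatrix:
    base = rng.gamma(2.0, mean / 2.0, size=n_genes)
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    vals = rng.poisson(base[:, None] * depth[None, :]).astype(float)
    return ExpressionMatrix(
        vals,
        [f"g{i}" for i in range(n_genes)],
        [f"s{j}" for j in range(n_samples)],
        "counts",
    )


def make_meta(visits_by_patient: dict[str, list[int]]) -> list[SampleMeta]:
    meta = []
    for pid, ranks in visits_by_patient.items():
        for r in ranks:
            meta.append(
                SampleMeta(
                    sample_id=f"{pid}_v{r}", patient_id=pid, visit_rank=r,
                    visit_label=f"V{r}",
                )
            )
    return meta


def random_geometric_flow_graph(rng, n_nodes=20, k=4) -> tuple[FlowGraph, np.ndarray]:
    """Connected directed graph over random 2-D points: chain + kNN union,
    both arc directions, Euclidean costs. Returns (graph, points)."""
    pts = rng.uniform(0, 10, size=(n_nodes, 2))
    pairs = set()
    order = np.argsort(pts[:, 0], kind="stable")
    for a, b in zip(order, order[1:]):  # chain guarantees connectivity
        pairs.add((min(a, b), max(a, b)))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    for u in range(n_nodes):
        for v in np.argsort(d[u], kind="stable")[1: k + 1]:
            pairs.add((min(u, int(v)), max(u, int(v))))
    arcs, cost = [], []
    for (i, j) in sorted(pairs):
        arcs.extend([(i, j), (j, i)])
        cost.extend([d[i, j], d[i, j]])
    return FlowGraph(
        nodes=[f"n{i}" for i in range(n_nodes)], arcs=arcs, cost=np.array(cost)
    ), pts


def check_solution_residuals(g, commodities, sol, cfg, tol=1e-6):
    """Conservation, edge-capacity and node-capacity residuals."""
    total = {a: 0.0 for a in g.arcs}
    for c in commodities:
        s, t = g.node_index(c.source), g.node_index(c.sink)
        net = np.zeros(g.n_nodes)
        for (u, v), f in sol.flows[c.id].items():
            assert -tol <= f <= 1 + tol
            net[u] += f
            net[v] -= f
            total[(u, v)] += f
        expect = np.zeros(g.n_nodes)
        expect[s], expect[t] = c.demand, -c.demand
        assert np.max(np.abs(net - expect)) < tol, "flow conservation violated"
    if np.isfinite(cfg.edge_capacity):
        assert max(total.values(), default=0.0) <= cfg.edge_capacity + tol
    if cfg.node_capacity is not None:
        inbound = np.zeros(g.n_nodes)
        for c in commodities:
            for (u, v), f in sol.flows[c.id].items():
                inbound[v] += f
        assert inbound.max() <= cfg.node_capacity + tol
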