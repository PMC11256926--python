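"""Capacity-constrained multi-commodity flow over the sample graph.

Each consecutive-visit pair of one patient is a commodity (source = earlier
visit, sink = later visit, demand 1). Commodities are routed over the
directed completion of the connectivity graph with arc costs equal to the
Euclidean distance between PCA embeddings. The fractional LP

    minimize   U = sum_{(u,v)} c(u,v) * sum_i f_i(u,v)
    subject to sum_i f_i(u,v) <= C                  (arc capacity)
               net flow of commodity i = +1 / -1 / 0 at source / sink / else
               sum_i sum_u f_i(u,w) <= N            (node capacity, optional)
               0 <= f_i(u,v) <= 1

is solved with HiGHS; per-patient paths are then recovered from the optimal
flows by bottleneck path decomposition. An optional hop limit restricts each
commodity to arcs lying on some source-to-sink path of at most l hops, which
shrinks the LP without affecting optimality when l is large enough.
"""

from __future__ import annotations

import json
import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from cohortflow.data_io import SampleMeta
from cohortflow.manifold import ConnectivityGraph, Embedding

logger = logging.getLogger(__name__)

FLOW_EPS = 1e-6


@dataclass
class FlowGraph:
    """Directed graph over samples with symmetric Euclidean arc costs."""

    nodes: list[str]
    arcs: list[tuple[int, int]]  # node indices; both directions present
    cost: np.ndarray  # aligned with arcs, >= 0

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=float)
        if len(self.arcs) != self.cost.size:
            raise ValueError("arcs and cost misaligned")
        if np.any(self.cost < 0):
            raise ValueError("arc costs must be non-negative")
        self._index = {a: k for k, a in enumerate(self.arcs)}
        self._out: dict[int, list[int]] = {}
        self._in: dict[int, list[int]] = {}
        for u, v in self.arcs:
            if u == v:
                raise ValueError("self-arcs are not allowed")
            self._out.setdefault(u, []).append(v)
            self._in.setdefault(v, []).append(u)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self, sample_id: str) -> int:
        return self.nodes.index(sample_id)

    def arc_index(self, u: int, v: int) -> int:
        return self._index[(u, v)]

    def successors(self, u: int) -> list[int]:
        return self._out.get(u, [])

    def predecessors(self, v: int) -> list[int]:
        return self._in.get(v, [])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        for (u, v), c in zip(self.arcs, self.cost):
            g.add_edge(u, v, weight=float(c))
        return g


def build_flow_graph(g: ConnectivityGraph, e: Embedding) -> FlowGraph:
    """Expand each undirected connectivity edge into two opposite arcs with
    cost equal to the Euclidean distance between the endpoint embeddings."""
    if g.nodes != e.sample_ids:
        raise ValueError("connectivity graph and embedding sample order differ")
    arcs: list[tuple[int, int]] = []
    cost: list[float] = []
    for (i, j) in sorted(g.edges):
        d = float(np.linalg.norm(e.coords[i] - e.coords[j]))
        arcs.extend([(i, j), (j, i)])
        cost.extend([d, d])
    return FlowGraph(nodes=list(g.nodes), arcs=arcs, cost=np.array(cost))


@dataclass
class Commodity:
    """One consecutive-visit transition of one patient."""

    id: int
    source: str
    sink: str
    demand: float = 1.0
    patient_id: str = ""
    transition_rank: int = 0

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValueError("commodity source and sink must differ")


@dataclass
class CapacityConfig:
    """Edge capacity C, optional node capacity N and hop limit l."""

    edge_capacity: float = 1.0
    node_capacity: float | None = None
    hop_limit: int | None = None

    def __post_init__(self) -> None:
        if self.edge_capacity <= 0:
            raise ValueError("edge capacity must be positive")
        if self.node_capacity is not None and self.node_capacity <= 0:
            raise ValueError("node capacity must be positive")
        if self.hop_limit is not None and self.hop_limit < 1:
            raise ValueError("hop limit must be >= 1")


@dataclass
class FlowSolution:
    """Optimal per-commodity arc flows and objective U."""

    status: str  # "optimal" | "infeasible"
    objective: float
    flows: dict[int, dict[tuple[int, int], float]]  # commodity id -> arc -> flow
    commodities: list[Commodity]
    dropped_commodities: list[tuple[Commodity, str]] = field(default_factory=list)
    message: str = ""

    def to_json(self, g: FlowGraph) -> str:
        payload = {
            "status": self.status,
            "objective": self.objective,
            "flows": {
                str(cid): {
                    f"{g.nodes[u]}->{g.nodes[v]}": f for (u, v), f in arcs.items()
                }
                for cid, arcs in self.flows.items()
            },
            "dropped": [
                {"commodity": c.id, "source": c.source, "sink": c.sink, "reason": r}
                for c, r in self.dropped_commodities
            ],
        }
        return json.dumps(payload, indent=2)


@dataclass
class PatientPath:
    """The recovered sample-level path of one commodity."""

    commodity_id: int
    nodes: list[str]
    cost: float
    patient_id: str = ""
    transition_rank: int = 0


def build_commodities(meta: list[SampleMeta]) -> list[Commodity]:
    """One commodity per consecutive observed visit pair per patient,
    ordered by (patient, transition rank). A patient with T visits yields
    T-1 commodities; single-visit patients yield none."""
    by_patient: dict[str, list[SampleMeta]] = {}
    for s in meta:
        by_patient.setdefault(s.patient_id, []).append(s)
    commodities: list[Commodity] = []
    cid = 0
    for pid in sorted(by_patient):
        visits = sorted(by_patient[pid], key=lambda s: s.visit_rank)
        if len(visits) < 2:
            logger.info("patient %s has a single visit; no commodities", pid)
            continue
        for rank, (a, b) in enumerate(zip(visits, visits[1:])):
            commodities.append(
                Commodity(
                    id=cid,
                    source=a.sample_id,
                    sink=b.sample_id,
                    demand=1.0,
                    patient_id=pid,
                    transition_rank=rank,
                )
            )
            cid += 1
    return commodities


def _bfs_hops(g: FlowGraph, start: int, reverse: bool = False) -> np.ndarray:
    """Directed BFS hop distances from ``start`` (or to it when reverse)."""
    dist = np.full(g.n_nodes, np.inf)
    dist[start] = 0
    q = deque([start])
    step = g.predecessors if reverse else g.successors
    while q:
        u = q.popleft()
        for v in step(u):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def restrict_arcs(g: FlowGraph, c: Commodity, hop_limit: int) -> list[tuple[int, int]]:
    """Arcs lying on some source-to-sink walk of at most ``hop_limit`` hops:
    exactly those (u, v) with hops(s, u) + 1 + hops(v, t) <= l."""
    if hop_limit < 1:
        raise ValueError("hop_limit must be >= 1")
    s, t = g.node_index(c.source), g.node_index(c.sink)
    d_from_s = _bfs_hops(g, s)
    d_to_t = _bfs_hops(g, t, reverse=True)
    return [
        (u, v)
        for (u, v) in g.arcs
        if d_from_s[u] + 1 + d_to_t[v] <= hop_limit
    ]


def _has_path(g: FlowGraph, c: Commodity, hop_limit: int | None) -> bool:
    s, t = g.node_index(c.source), g.node_index(c.sink)
    d = _bfs_hops(g, s)
    if hop_limit is None:
        return bool(np.isfinite(d[t]))
    return bool(d[t] <= hop_limit)


def drop_unreachable(
    commodities: list[Commodity], g: FlowGraph, hop_limit: int | None = None
) -> tuple[list[Commodity], list[tuple[Commodity, str]]]:
    """Partition commodities into (reachable, dropped-with-reason); a
    commodity is dropped when no source-to-sink path exists within the hop
    limit."""
    kept: list[Commodity] = []
    dropped: list[tuple[Commodity, str]] = []
    for c in commodities:
        if _has_path(g, c, hop_limit):
            kept.append(c)
        else:
            dropped.append((c, "unreachable"))
    if dropped:
        logger.warning(
            "dropped %d/%d unreachable commodities (%.1f%%)",
            len(dropped), len(commodities), 100 * len(dropped) / len(commodities),
        )
    return kept, dropped


def solve_flow(
    g: FlowGraph, commodities: list[Commodity], cfg: CapacityConfig | None = None
) -> FlowSolution:
    """Solve the fractional multi-commodity flow LP.

    The node-capacity constraint counts all inbound flow at a node,
    including flow terminating there. Infeasibility is returned as a status
    (with a hint to raise C), not raised.
    """
    cfg = cfg or CapacityConfig()
    if not commodities:
        raise ValueError("no commodities to route")
    # per-commodity allowed arc set (hop-restricted corridors)
    arc_sets: list[list[int]] = []
    for c in commodities:
        if cfg.hop_limit is not None:
            allowed = restrict_arcs(g, c, cfg.hop_limit)
            arcs = [g.arc_index(u, v) for (u, v) in allowed]
        else:
            arcs = list(range(len(g.arcs)))
        if not arcs:
            raise ValueError(
                f"commodity {c.id} ({c.source}->{c.sink}) has an empty corridor; "
                "run drop_unreachable first"
            )
        arc_sets.append(arcs)

    # variable layout: offsets[i] + position within arc_sets[i]
    offsets = np.cumsum([0] + [len(a) for a in arc_sets])
    n_var = int(offsets[-1])
    obj = np.concatenate([g.cost[a] for a in arc_sets])

    eq_rows: list[int] = []
    eq_cols: list[int] = []
    eq_data: list[float] = []
    eq_rhs: list[float] = []
    row = 0
    for i, c in enumerate(commodities):
        s, t = g.node_index(c.source), g.node_index(c.sink)
        node_rows: dict[int, int] = {}
        touched: list[int] = []
        for k, aidx in enumerate(arc_sets[i]):
            u, v = g.arcs[aidx]
            for node, sign in ((u, 1.0), (v, -1.0)):
                if node not in node_rows:
                    node_rows[node] = row
                    touched.append(node)
                    row += 1
                eq_rows.append(node_rows[node])
                eq_cols.append(offsets[i] + k)
                eq_data.append(sign)
        for node in touched:
            eq_rhs.append(
                c.demand if node == s else (-c.demand if node == t else 0.0)
            )
        if s not in node_rows or t not in node_rows:
            raise ValueError(
                f"commodity {c.id} corridor misses its own endpoints; "
                "run drop_unreachable first"
            )
    a_eq = coo_matrix((eq_data, (eq_rows, eq_cols)), shape=(row, n_var))
    b_eq = np.array(eq_rhs)

    ub_rows: list[int] = []
    ub_cols: list[int] = []
    ub_data: list[float] = []
    ub_rhs: list[float] = []
    urow = 0
    # per-arc sum <= C is implied by the [0,1] bounds when C >= #commodities
    if np.isfinite(cfg.edge_capacity) and cfg.edge_capacity < len(commodities):
        arc_row: dict[int, int] = {}
        for i in range(len(commodities)):
            for k, aidx in enumerate(arc_sets[i]):
                if aidx not in arc_row:
                    arc_row[aidx] = urow
                    ub_rhs.append(cfg.edge_capacity)
                    urow += 1
                ub_rows.append(arc_row[aidx])
                ub_cols.append(offsets[i] + k)
                ub_data.append(1.0)
    if cfg.node_capacity is not None and np.isfinite(cfg.node_capacity):
        node_row: dict[int, int] = {}
        for i in range(len(commodities)):
            for k, aidx in enumerate(arc_sets[i]):
                _, v = g.arcs[aidx]
                if v not in node_row:
                    node_row[v] = urow
                    ub_rhs.append(cfg.node_capacity)
                    urow += 1
                ub_rows.append(node_row[v])
                ub_cols.append(offsets[i] + k)
                ub_data.append(1.0)
    a_ub = (
        coo_matrix((ub_data, (ub_rows, ub_cols)), shape=(urow, n_var))
        if urow
        else None
    )
    b_ub = np.array(ub_rhs) if urow else None

    res = linprog(
        obj,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0.0, 1.0),
        method="highs-ds",  # dual simplex: fastest here, returns vertex solutions
        options={"presolve": True},
    )
    if res.status == 2:
        msg = (
            "LP infeasible under the given capacities; consider raising the "
            f"edge capacity above C={cfg.edge_capacity:g} (congested arcs or "
            "nodes cannot carry all commodities)"
        )
        logger.warning(msg)
        return FlowSolution(
            status="infeasible", objective=math.nan, flows={},
            commodities=list(commodities), message=msg,
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")

    flows: dict[int, dict[tuple[int, int], float]] = {}
    for i, c in enumerate(commodities):
        arcflow: dict[tuple[int, int], float] = {}
        x = res.x[offsets[i]: offsets[i + 1]]
        for k, aidx in enumerate(arc_sets[i]):
            f = float(np.clip(x[k], 0.0, 1.0))
            if f > 1e-9:
                arcflow[g.arcs[aidx]] = f
        flows[c.id] = arcflow
    return FlowSolution(
        status="optimal",
        objective=float(res.fun),
        flows=flows,
        commodities=list(commodities),
    )


# ---------------------------------------------------------------------------
# Path extraction (flow decomposition)
# ---------------------------------------------------------------------------

def _widest_path(
    flow: dict[tuple[int, int], float], s: int, t: int
) -> list[int] | None:
    """Maximum-bottleneck s->t path over the arcs carrying flow, ties broken
    lexicographically on node indices (modified Dijkstra maximizing the
    minimum arc flow)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes = {s, t}
    for (u, v), f in flow.items():
        adj.setdefault(u, []).append((v, f))
        nodes.update((u, v))
    best = {n: -1.0 for n in nodes}
    prev: dict[int, int] = {}
    best[s] = math.inf
    visited: set[int] = set()
    while True:
        cand = [n for n in nodes if n not in visited and best[n] > 0]
        if not cand:
            break
        # widest first; lexicographic node index breaks ties deterministically
        u = min(cand, key=lambda n: (-best[n], n))
        if u == t:
            break
        visited.add(u)
        for v, f in sorted(adj.get(u, [])):
            b = min(best[u], f)
            if b > best[v]:
                best[v] = b
                prev[v] = u
    if best[t] <= 0:
        return None
    path = [t]
    while path[-1] != s:
        path.append(prev[path[-1]])
    return path[::-1]


def decompose_flow(
    flow: dict[tuple[int, int], float], s: int, t: int, residual_tol: float = FLOW_EPS
) -> list[tuple[list[int], float]]:
    """Decompose one commodity's arc flow into weighted s->t paths by
    iteratively stripping the maximum-bottleneck path. Raises when more than
    ``residual_tol`` demand remains unaccounted."""
    remaining = {a: f for a, f in flow.items() if f > 1e-9}
    paths: list[tuple[list[int], float]] = []
    routed = 0.0
    while routed < 1.0 - residual_tol:
        path = _widest_path(remaining, s, t)
        if path is None:
            raise ValueError(
                f"flow decomposition left {1.0 - routed:.3g} of the demand "
                "unaccounted; solver tolerance problem"
            )
        w = min(remaining[(u, v)] for u, v in zip(path, path[1:]))
        w = min(w, 1.0 - routed)
        for u, v in zip(path, path[1:]):
            remaining[(u, v)] -= w
            if remaining[(u, v)] <= 1e-9:
                del remaining[(u, v)]
        paths.append((path, w))
        routed += w
    return paths


def _threshold_path(
    flow: dict[tuple[int, int], float], s: int, t: int, threshold: float
) -> list[int] | None:
    """If arcs with flow >= threshold form a single s->t path, return it."""
    strong = {a for a, f in flow.items() if f >= threshold}
    nxt: dict[int, int] = {}
    for u, v in strong:
        if u in nxt:
            return None  # branching
        nxt[u] = v
    path = [s]
    seen = {s}
    while path[-1] != t:
        u = path[-1]
        if u not in nxt or nxt[u] in seen:
            return None
        path.append(nxt[u])
        seen.add(nxt[u])
    if len(path) - 1 != len(strong):
        return None  # disconnected strong arcs left over
    return path


def extract_paths(
    sol: FlowSolution, g: FlowGraph, flow_threshold: float = 0.5
) -> list[PatientPath]:
    """One sample-level path per commodity from the optimal flows.

    Arcs with flow >= ``flow_threshold`` are followed from the source; when
    they do not form a single source-to-sink path the flow is decomposed
    into weighted paths and the highest-weight one is returned (ties:
    lexicographically smaller node-id sequence).
    """
    if sol.status != "optimal":
        raise ValueError("paths can only be extracted from an optimal solution")
    out: list[PatientPath] = []
    for c in sol.commodities:
        s, t = g.node_index(c.source), g.node_index(c.sink)
        flow = sol.flows[c.id]
        path = _threshold_path(flow, s, t, flow_threshold)
        if path is None:
            pieces = decompose_flow(flow, s, t)
            names = [[g.nodes[n] for n in p] for p, _ in pieces]
            best = max(
                range(len(pieces)), key=lambda k: (pieces[k][1], _neg_lex(names[k]))
            )
            path = pieces[best][0]
        cost = sum(
            g.cost[g.arc_index(u, v)] for u, v in zip(path, path[1:])
        )
        out.append(
            PatientPath(
                commodity_id=c.id,
                nodes=[g.nodes[n] for n in path],
                cost=float(cost),
                patient_id=c.patient_id,
                transition_rank=c.transition_rank,
            )
        )
    return out


class _neg_lex:
    """Sort key that prefers lexicographically *smaller* sequences under max()."""

    def __init__(self, seq: list[str]):
        self.seq = seq

    def __lt__(self, other: "_neg_lex") -> bool:
        return self.seq > other.seq

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_lex) and self.seq == other.seq


def write_paths_tsv(paths: list[PatientPath], path) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\ttransition_rank\tnodes\tcost\n")
        for p in paths:
            fh.write(
                f"{p.patient_id}\t{p.transition_rank}\t{','.join(p.nodes)}\t{p.cost:.10g}\n"
            )
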