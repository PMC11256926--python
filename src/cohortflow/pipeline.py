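"""End-to-end orchestration: load -> normalize -> embed -> graph -> states
-> commodities -> flow -> paths -> diagram -> trajectories."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from cohortflow import data_io
from cohortflow.data_io import ExpressionMatrix, SampleMeta
from cohortflow.flow_core import (
    CapacityConfig,
    FlowSolution,
    PatientPath,
    build_commodities,
    build_flow_graph,
    drop_unreachable,
    extract_paths,
    solve_flow,
    write_paths_tsv,
)
from cohortflow.manifold import (
    ConnectivityGraph,
    Embedding,
    StateAssignment,
    fuzzy_graph,
    leiden_states,
    pca_embed,
    select_n_neighbors,
)
from cohortflow.state_diagram import (
    StateDiagram,
    Trajectory,
    build_diagram,
    prune_diagram,
    top_trajectories,
    write_trajectories_tsv,
)

logger = logging.getLogger(__name__)


class InfeasibleFlowError(RuntimeError):
    """Raised by run_pipeline when the flow LP is infeasible under the
    configured capacities."""


_CONFIG_FIELDS: set[str] | None = None


@dataclass
class RunConfig:
    """All pipeline parameters plus provenance.

    Defaults: CPM filter >0.25 in >=1% of samples, edge capacity C=1
    (escalated automatically on congested cohorts), node capacity unset,
    demand 1 per commodity, hop limit l optional.
    """

    expr_path: str = ""
    meta_path: str = ""
    out_dir: str = ""
    fmt: str = "delimited"
    data_kind: str = "counts"
    cpm_threshold: float = 0.25
    min_fraction: float = 0.01
    n_pcs: int = 50
    log_transform: bool | None = None  # None: log1p for counts, off otherwise
    n_neighbors: int | None = None  # None: smallest ladder value giving a connected graph
    resolution: float = 1.0
    edge_capacity: float = 1.0
    max_edge_capacity: float | None = None  # retry with C+1 up to this on infeasibility
    node_capacity: float | None = None
    hop_limit: int | None = None
    flow_threshold: float = 0.5
    walk_length: int = 2
    top_k: int = 3
    prune_mass: float = 0.5
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed split from the master seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        global _CONFIG_FIELDS
        if _CONFIG_FIELDS is None:
            _CONFIG_FIELDS = set(cls.__dataclass_fields__)
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        from cohortflow import __version__

        payload = asdict(self)
        payload["provenance"] = {
            "tool_version": __version__,
            "config_hash": self.config_hash(),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class PipelineResult:
    matrix: ExpressionMatrix
    meta: list[SampleMeta]
    embedding: Embedding
    graph: ConnectivityGraph
    states: StateAssignment
    solution: FlowSolution
    paths: list[PatientPath]
    diagram: StateDiagram
    pruned_diagram: StateDiagram
    trajectories: list[Trajectory]
    dropped_fraction: float
    timings: dict[str, float] = field(default_factory=dict)


def preprocess(
    m: ExpressionMatrix, cfg: RunConfig
) -> tuple[ExpressionMatrix, dict[str, float] | None]:
    """Gene filter + dedup + TMM for counts; dedup only for pre-normalized
    (e.g. RMA microarray) matrices. Returns (normalized matrix, factors)."""
    if m.data_kind == data_io.COUNTS:
        m = data_io.filter_genes_cpm(m, cfg.cpm_threshold, cfg.min_fraction)
        m = data_io.dedupe_genes(m)
        factors = data_io.tmm_factors(m)
        return data_io.normalize_counts(m, factors), factors
    return data_io.dedupe_genes(m), None


def run_pipeline(
    cfg: RunConfig,
    matrix: ExpressionMatrix | None = None,
    meta: list[SampleMeta] | None = None,
) -> PipelineResult:
    """Execute the full trajectory-inference pipeline.

    Inputs are read from ``cfg.expr_path`` / ``cfg.meta_path`` unless an
    in-memory (matrix, meta) pair is given. When ``cfg.out_dir`` is set,
    every intermediate artifact is written there together with the resolved
    configuration.
    """
    timings: dict[str, float] = {}

    def clock(stage: str, start: float) -> None:
        timings[stage] = time.perf_counter() - start
        logger.info("stage %s: %.2fs", stage, timings[stage])

    t0 = time.perf_counter()
    if matrix is None or meta is None:
        matrix, meta = data_io.load_dataset(
            cfg.expr_path, cfg.meta_path, fmt=cfg.fmt, data_kind=cfg.data_kind
        )
    clock("load", t0)

    t0 = time.perf_counter()
    norm, factors = preprocess(matrix, cfg)
    clock("preprocess", t0)

    t0 = time.perf_counter()
    log_tf = cfg.log_transform
    if log_tf is None:
        log_tf = matrix.data_kind == data_io.COUNTS
    emb = pca_embed(norm, d=cfg.n_pcs, log_transform=log_tf, seed=cfg.stage_seed("pca"))
    if cfg.n_neighbors is None:
        chosen_k, graph = select_n_neighbors(emb)
        cfg = replace(cfg, n_neighbors=chosen_k)
    else:
        graph = fuzzy_graph(emb, n_neighbors=cfg.n_neighbors, seed=cfg.stage_seed("graph"))
    states = leiden_states(graph, resolution=cfg.resolution, seed=cfg.stage_seed("leiden"))
    clock("states", t0)

    t0 = time.perf_counter()
    fg = build_flow_graph(graph, emb)
    commodities = build_commodities(meta)
    kept, dropped = drop_unreachable(commodities, fg, cfg.hop_limit)
    dropped_fraction = len(dropped) / len(commodities) if commodities else 0.0
    if dropped:
        logger.warning(
            "%d/%d commodities unreachable (%.1f%%)",
            len(dropped), len(commodities), 100 * dropped_fraction,
        )
    # escalate C on infeasibility: doubling, capped at the number of
    # commodities, where the arc-capacity constraint is vacuous and every
    # reachable commodity can route, so the loop always terminates.
    capacity = cfg.edge_capacity
    max_capacity = cfg.max_edge_capacity
    if max_capacity is None:
        max_capacity = max(cfg.edge_capacity, len(kept))
    while True:
        cap = CapacityConfig(
            edge_capacity=capacity,
            node_capacity=cfg.node_capacity,
            hop_limit=cfg.hop_limit,
        )
        sol = solve_flow(fg, kept, cap)
        if sol.status == "optimal" or capacity >= max_capacity:
            break
        capacity = min(capacity * 2, max_capacity)
        logger.warning("flow LP infeasible; escalating edge capacity to C=%g", capacity)
    sol.dropped_commodities = dropped
    if sol.status != "optimal":
        raise InfeasibleFlowError(sol.message)
    paths = extract_paths(sol, fg, flow_threshold=cfg.flow_threshold)
    clock("flow", t0)

    t0 = time.perf_counter()
    diagram = build_diagram(paths, states)
    pruned = prune_diagram(diagram, cfg.prune_mass)
    trajectories = top_trajectories(diagram, length=cfg.walk_length, k=cfg.top_k)
    clock("diagram", t0)

    result = PipelineResult(
        matrix=norm,
        meta=meta,
        embedding=emb,
        graph=graph,
        states=states,
        solution=sol,
        paths=paths,
        diagram=diagram,
        pruned_diagram=pruned,
        trajectories=trajectories,
        dropped_fraction=dropped_fraction,
        timings=timings,
    )
    if cfg.out_dir:
        _write_artifacts(cfg, result, fg, factors)
    return result


def _write_artifacts(cfg: RunConfig, res: PipelineResult, fg, factors) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.resolved.yaml")
    data_io.write_expression(res.matrix, out / "normalized.tsv")
    data_io.write_meta(res.meta, out / "meta.tsv")
    if factors is not None:
        data_io.write_factors(factors, out / "tmm_factors.tsv")
    res.graph.write_edgelist(out / "connectivity.tsv")
    res.graph.write_graphml(out / "connectivity.graphml")
    res.states.write_tsv(out / "states.tsv")
    (out / "flow.json").write_text(res.solution.to_json(fg))
    write_paths_tsv(res.paths, out / "paths.tsv")
    (out / "diagram.json").write_text(res.diagram.to_json())
    (out / "diagram_pruned.json").write_text(res.pruned_diagram.to_json())
    res.pruned_diagram.write_dot(out / "diagram_pruned.dot")
    write_trajectories_tsv(res.trajectories, out / "trajectories.tsv")
    logger.info("artifacts written to %s", out)
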