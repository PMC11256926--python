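"""Synthetic short-time-series cohorts with planted state trajectories.

A cohort of P patients is generated around a small set of latent disease
states. Each patient follows one of a few planted state sequences
("endotypes"), observes only a subset of the sequence's positions (few
clinic visits per patient, so intermediate states are routinely skipped),
and emits expression as a fixed random linear map of its noisy latent
positions passed through a softplus and scaled to count-like magnitudes.
The generator is fully deterministic given its seed and carries the ground
truth needed to score trajectory recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np

from cohortflow.data_io import ExpressionMatrix, SampleMeta
from cohortflow.state_diagram import StateDiagram, Trajectory, collapse_repeats


def chain_branch_centers(n_states: int = 6, separation: float = 4.0) -> np.ndarray:
    """Default 2-D state geometry: a chain of ``n_states - 2`` states with
    two branch states forking off the chain's end. Consecutive chain centers
    sit ``separation`` apart; the two branch endpoints are symmetric about
    the chain axis. Models a shared disease course with divergent outcomes.
    """
    if n_states < 3:
        raise ValueError("need at least 3 states for a chain with branches")
    n_chain = n_states - 2
    centers = np.zeros((n_states, 2))
    for i in range(n_chain):
        centers[i] = (i, 0.0)
    centers[n_chain] = (n_chain, 1.0)
    centers[n_chain + 1] = (n_chain, -1.0)
    centers *= separation
    # center at the origin: keeps every state in the quasi-linear regime of
    # the softplus/log expression map instead of pushing the chain's far end
    # into saturation
    return centers - centers.mean(axis=0)


@dataclass
class CohortSpec:
    """Parameters of the planted-trajectory cohort generator.

    Defaults describe the reference simulation regime: 60 patients, two
    equally likely endotypes sharing a 4-state course and diverging at the
    final state (5-state planted paths over 6 states), 3 observed visits
    per patient (first and last trajectory positions plus one random middle
    position), latent Gaussian noise well below the center separation.
    """

    n_states: int = 6
    state_centers: np.ndarray | None = None  # default: chain_branch_centers
    endotypes: list[list[int]] = field(
        default_factory=lambda: [[0, 1, 2, 3, 4], [0, 1, 2, 3, 5]]
    )
    endotype_weights: list[float] = field(default_factory=lambda: [0.5, 0.5])
    n_patients: int = 60
    visits_per_patient: int = 3
    observed_visits: str = "endpoints_plus_random"  # or "all", "random"
    noise_sd: float = 0.5
    center_separation: float = 4.0
    n_genes: int = 150
    loading_matrix: np.ndarray | None = None  # default: random unit-scale map
    expression_scale: float = 50.0
    dropout_visit_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state_centers is None:
            self.state_centers = chain_branch_centers(
                self.n_states, self.center_separation
            )
        self.state_centers = np.asarray(self.state_centers, dtype=float)
        if self.state_centers.shape[0] != self.n_states:
            raise ValueError("state_centers rows must match n_states")
        for seq in self.endotypes:
            if any(a == b for a, b in zip(seq, seq[1:])):
                raise ValueError("endotype sequences must have no consecutive repeats")
            if any(not 0 <= s < self.n_states for s in seq):
                raise ValueError("endotype state out of range")
        w = np.asarray(self.endotype_weights, dtype=float)
        if w.size != len(self.endotypes) or abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("endotype_weights must be a simplex vector over endotypes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.visits_per_patient < 2:
            raise ValueError("need at least 2 visits per patient")
        if not 0 <= self.dropout_visit_prob < 1:
            raise ValueError("dropout_visit_prob must be in [0, 1)")

    @property
    def d_latent(self) -> int:
        return self.state_centers.shape[1]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort spec keys: {sorted(unknown)}")
        for key in ("state_centers", "loading_matrix"):
            if raw.get(key) is not None:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = {
            k: getattr(self, k) for k in self.__dataclass_fields__
            if k not in ("state_centers", "loading_matrix")
        }
        payload["state_centers"] = self.state_centers.tolist()
        if self.loading_matrix is not None:
            payload["loading_matrix"] = np.asarray(self.loading_matrix).tolist()
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class GroundTruth:
    """Planted structure behind a simulated cohort."""

    endotype_of_patient: dict[str, int]
    endotype_sequences: list[list[int]]
    latent_positions: dict[str, np.ndarray]  # sample_id -> latent coords
    planted_diagram: StateDiagram

    def to_json(self) -> str:
        return json.dumps(
            {
                "endotype_of_patient": self.endotype_of_patient,
                "endotype_sequences": self.endotype_sequences,
                "latent_positions": {
                    k: v.tolist() for k, v in self.latent_positions.items()
                },
            },
            indent=2,
        )


def _planted_diagram(spec: CohortSpec) -> StateDiagram:
    n = spec.n_states
    counts = np.zeros((n, n), dtype=int)
    init = np.zeros(n)
    final = np.zeros(n)
    for seq, w in zip(spec.endotypes, spec.endotype_weights):
        for a, b in zip(seq, seq[1:]):
            counts[a, b] += 1
        init[seq[0]] += w
        final[seq[-1]] += w
    probs = np.zeros((n, n))
    tot = counts.sum(axis=1)
    nz = tot > 0
    probs[nz] = counts[nz] / tot[nz, None]
    return StateDiagram(
        n_states=n,
        transition_counts=counts,
        transition_probs=probs,
        init_probs=init / init.sum(),
        final_probs=final / final.sum(),
    )


def _observed_positions(
    spec: CohortSpec, seq_len: int, rng: np.random.Generator
) -> list[int]:
    v = min(spec.visits_per_patient, seq_len)
    if spec.observed_visits == "all" or v == seq_len:
        return list(range(seq_len))
    if spec.observed_visits == "endpoints_plus_random":
        middle = rng.choice(np.arange(1, seq_len - 1), size=v - 2, replace=False)
        return sorted({0, seq_len - 1, *middle.tolist()})
    if spec.observed_visits == "random":
        pos = rng.choice(np.arange(seq_len), size=v, replace=False)
        return sorted(pos.tolist())
    raise ValueError(f"unknown observed_visits rule {spec.observed_visits!r}")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, list[SampleMeta], GroundTruth]:
    """Draw a cohort from the planted-trajectory model.

    Per patient: draw an endotype by weight, pick observed trajectory
    positions, place each observed visit at the corresponding state center
    plus isotropic Gaussian noise, then map latent coordinates to
    count-like expression through a fixed random linear map and softplus.
    Visits are dropped independently with ``dropout_visit_prob``; a patient
    left with fewer than 2 visits is redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.loading_matrix is None:
        loading = rng.normal(size=(spec.d_latent, spec.n_genes)) / np.sqrt(spec.d_latent)
    else:
        loading = np.asarray(spec.loading_matrix, dtype=float)
        if loading.shape != (spec.d_latent, spec.n_genes):
            raise ValueError("loading_matrix must be d_latent x n_genes")

    meta: list[SampleMeta] = []
    latents: list[np.ndarray] = []
    sample_ids: list[str] = []
    endo_of: dict[str, int] = {}
    latent_of: dict[str, np.ndarray] = {}

    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        for _attempt in range(1000):
            e = int(rng.choice(len(spec.endotypes), p=spec.endotype_weights))
            seq = spec.endotypes[e]
            positions = _observed_positions(spec, len(seq), rng)
            if spec.dropout_visit_prob > 0:
                keep = rng.random(len(positions)) >= spec.dropout_visit_prob
                positions = [pos for pos, k in zip(positions, keep) if k]
            if len(positions) >= 2:
                break
        else:
            raise ValueError(
                "could not draw >= 2 observed visits per patient; "
                "lower dropout_visit_prob"
            )
        endo_of[pid] = e
        for pos in positions:
            sid = f"{pid}_V{pos}"
            z = spec.state_centers[seq[pos]] + rng.normal(
                scale=spec.noise_sd, size=spec.d_latent
            )
            sample_ids.append(sid)
            latents.append(z)
            latent_of[sid] = z
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    patient_id=pid,
                    visit_rank=pos,
                    visit_label=f"V{pos}",
                    covariates={"planted_state": int(seq[pos]), "endotype": e},
                )
            )

    z = np.vstack(latents)  # samples x d_latent
    expr = np.log1p(np.exp(np.clip(z @ loading, -500, 500)))  # softplus
    expr = expr * spec.expression_scale
    m = ExpressionMatrix(
        values=expr.T,
        gene_ids=[f"G{j:04d}" for j in range(spec.n_genes)],
        sample_ids=sample_ids,
        data_kind="counts",
    )
    truth = GroundTruth(
        endotype_of_patient=endo_of,
        endotype_sequences=[list(s) for s in spec.endotypes],
        latent_positions=latent_of,
        planted_diagram=_planted_diagram(spec),
    )
    return m, meta, truth


def recovery_score(
    inferred: list[Trajectory], truth: GroundTruth, k: int | None = None
) -> float:
    """Fraction of planted endotype sequences found among the top-k inferred
    trajectories, maximized over injective relabelings of the states
    (cluster labels are arbitrary)."""
    if not truth.endotype_sequences:
        raise ValueError("ground truth has no endotypes")
    top = inferred if k is None else inferred[:k]
    inferred_seqs = [tuple(t.states) for t in top]
    planted = [tuple(collapse_repeats(list(s))) for s in truth.endotype_sequences]
    planted_states = sorted({s for seq in planted for s in seq})
    inferred_states = sorted({s for seq in inferred_seqs for s in seq})
    # pad so an injective map always exists even if fewer labels were inferred
    pool = inferred_states + [
        -(i + 1) for i in range(max(0, len(planted_states) - len(inferred_states)))
    ]
    best = 0
    target = len(planted)
    for perm in permutations(pool, len(planted_states)):
        relabel = dict(zip(planted_states, perm))
        hits = sum(
            1
            for seq in planted
            if tuple(relabel[s] for s in seq) in inferred_seqs
        )
        if hits > best:
            best = hits
            if best == target:
                break
    return best / target


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json() + "\n")
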