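"""State-transition diagram aggregation and trajectory ranking.

Per-patient sample paths are mapped onto cluster states, consecutive
repeats collapsed, and all consecutive state pairs tallied into a
transition-count matrix. Initial / final state probabilities are estimated
from each patient's first / last observed visit. Likely disease
trajectories (endotypes) are ranked by

    score(s_0 .. s_L) = init[s_0] * prod_k P[s_k, s_{k+1}] * final[s_L]

via exact enumeration over repeat-free state sequences (state spaces here
are small, so enumeration replaces sampled random walks and is
deterministic).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from cohortflow.flow_core import PatientPath
from cohortflow.manifold import StateAssignment

ENUMERATION_BUDGET = 10_000_000


@dataclass
class StateDiagram:
    """Row-stochastic transition matrix with initial/final probabilities.

    The diagonal of ``transition_counts`` is zero by construction (repeated
    states are collapsed before counting). Rows with no outgoing counts are
    flagged absorbing and excluded from walk continuation.
    """

    n_states: int
    transition_counts: np.ndarray
    transition_probs: np.ndarray
    init_probs: np.ndarray
    final_probs: np.ndarray

    @property
    def absorbing(self) -> np.ndarray:
        return self.transition_counts.sum(axis=1) == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_states": self.n_states,
                "transition_counts": self.transition_counts.tolist(),
                "transition_probs": self.transition_probs.tolist(),
                "init_probs": self.init_probs.tolist(),
                "final_probs": self.final_probs.tolist(),
            },
            indent=2,
        )

    def write_dot(self, path) -> None:
        lines = ["digraph states {"]
        for s in range(self.n_states):
            lines.append(f'  {s} [label="state {s}"];')
        for s in range(self.n_states):
            for t in range(self.n_states):
                p = self.transition_probs[s, t]
                if p > 0:
                    lines.append(f'  {s} -> {t} [label="{p:.2f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class Trajectory:
    """A ranked state sequence with its walk probability."""

    states: list[int]
    score: float

    @property
    def length(self) -> int:
        return len(self.states) - 1

    def __str__(self) -> str:
        return "-".join(map(str, self.states))


def collapse_repeats(states: list[int]) -> list[int]:
    """Drop consecutive duplicates (``0-0-5`` becomes ``0-5``)."""
    return [s for k, s in enumerate(states) if k == 0 or s != states[k - 1]]


def build_diagram(paths: list[PatientPath], states: StateAssignment) -> StateDiagram:
    """Aggregate per-patient paths into a state diagram.

    Each path's node sequence is mapped to states and collapsed; every
    consecutive state pair increments the count matrix. Initial (final)
    probabilities come from the state of each patient's first (last)
    observed visit, taken from the patient's lowest- and highest-rank paths.
    """
    if not paths:
        raise ValueError("no paths to aggregate")
    n = states.n_states
    counts = np.zeros((n, n), dtype=int)
    for p in paths:
        seq = collapse_repeats([states.labels[s] for s in p.nodes])
        for a, b in zip(seq, seq[1:]):
            counts[a, b] += 1
    by_patient: dict[str, list[PatientPath]] = {}
    for p in paths:
        by_patient.setdefault(p.patient_id, []).append(p)
    init = np.zeros(n)
    final = np.zeros(n)
    for pid, plist in by_patient.items():
        plist.sort(key=lambda p: p.transition_rank)
        init[states.labels[plist[0].nodes[0]]] += 1
        final[states.labels[plist[-1].nodes[-1]]] += 1
    init /= init.sum()
    final /= final.sum()
    probs = np.zeros((n, n))
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    probs[nz] = counts[nz] / row_tot[nz, None]
    return StateDiagram(
        n_states=n,
        transition_counts=counts,
        transition_probs=probs,
        init_probs=init,
        final_probs=final,
    )


def trajectory_score(d: StateDiagram, seq: list[int]) -> float:
    p = d.init_probs[seq[0]]
    for a, b in zip(seq, seq[1:]):
        p *= d.transition_probs[a, b]
    return float(p * d.final_probs[seq[-1]])


def top_trajectories(d: StateDiagram, length: int, k: int = 3) -> list[Trajectory]:
    """Top-k state sequences with ``length`` transitions, by exact
    enumeration over all repeat-free sequences; ties rank lexicographically.
    """
    if length < 1 or k < 1:
        raise ValueError("length and k must be >= 1")
    n = d.n_states
    if n * (n - 1) ** length > ENUMERATION_BUDGET:
        raise ValueError(
            f"{n} states at length {length} exceeds the exact-enumeration "
            "budget; use sample_trajectories instead"
        )
    results: list[tuple[float, list[int]]] = []

    def extend(seq: list[int], prob: float) -> None:
        if len(seq) == length + 1:
            results.append((prob * d.final_probs[seq[-1]], list(seq)))
            return
        row = d.transition_probs[seq[-1]]
        for nxt in range(n):
            if nxt != seq[-1] and row[nxt] > 0:
                seq.append(nxt)
                extend(seq, prob * row[nxt])
                seq.pop()

    for s0 in range(n):
        if d.init_probs[s0] > 0:
            extend([s0], float(d.init_probs[s0]))
    results.sort(key=lambda r: (-r[0], r[1]))
    return [Trajectory(states=seq, score=score) for score, seq in results[:k]]


def sample_trajectories(
    d: StateDiagram, length: int, k: int, n_walks: int, seed: int = 0
) -> list[Trajectory]:
    """Seeded random-walk fallback for state spaces too large to enumerate:
    sample walks from init/transition probabilities and rank the distinct
    sequences seen by their exact score."""
    rng = np.random.default_rng(seed)
    n = d.n_states
    seen: set[tuple[int, ...]] = set()
    for _ in range(n_walks):
        s = int(rng.choice(n, p=d.init_probs))
        seq = [s]
        ok = True
        for _ in range(length):
            row = d.transition_probs[seq[-1]]
            if row.sum() <= 0:
                ok = False
                break
            seq.append(int(rng.choice(n, p=row)))
        if ok:
            seen.add(tuple(seq))
    scored = sorted(
        ((trajectory_score(d, list(t)), list(t)) for t in seen),
        key=lambda r: (-r[0], r[1]),
    )
    return [Trajectory(states=seq, score=score) for score, seq in scored[:k]]


def annotate_subsequences(trajectories: list[Trajectory]) -> list[str]:
    """Flag trajectories that are contiguous subsequences of a higher-ranked
    one (reported as annotation, never used to filter)."""
    notes = []
    for i, t in enumerate(trajectories):
        note = ""
        for j, other in enumerate(trajectories):
            if j == i or len(other.states) <= len(t.states):
                continue
            seq, sup = t.states, other.states
            if any(
                sup[k: k + len(seq)] == seq for k in range(len(sup) - len(seq) + 1)
            ):
                note = f"subsequence of {other}"
                break
        notes.append(note)
    return notes


def prune_diagram(d: StateDiagram, mass: float = 0.5) -> StateDiagram:
    """Per state, keep the fewest top outgoing edges whose cumulative weight
    reaches ``mass`` of the total outgoing weight; zero the rest and
    renormalize. Ties in weight are broken by state index (ascending)."""
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    probs = np.zeros_like(d.transition_probs)
    counts = np.zeros_like(d.transition_counts)
    for s in range(d.n_states):
        row = d.transition_probs[s]
        total = row.sum()
        if total <= 0:
            continue
        order = sorted(range(d.n_states), key=lambda t: (-row[t], t))
        cum = 0.0
        kept: list[int] = []
        for t in order:
            if row[t] <= 0:
                break
            kept.append(t)
            cum += row[t]
            if cum >= mass * total - 1e-12:
                break
        kept_mass = sum(row[t] for t in kept)
        for t in kept:
            probs[s, t] = row[t] / kept_mass
            counts[s, t] = d.transition_counts[s, t]
    return StateDiagram(
        n_states=d.n_states,
        transition_counts=counts,
        transition_probs=probs,
        init_probs=d.init_probs.copy(),
        final_probs=d.final_probs.copy(),
    )


def write_trajectories_tsv(trajectories: list[Trajectory], path) -> None:
    notes = annotate_subsequences(trajectories)
    with open(path, "w") as fh:
        fh.write("rank\tstates\tscore\tnote\n")
        for r, (t, note) in enumerate(zip(trajectories, notes), start=1):
            fh.write(f"{r}\t{t}\t{t.score:.10g}\t{note}\n")
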