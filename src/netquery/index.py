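"""Reference-based index over a target network.

The index is built in two steps.  Step I grows small reference subtrees of
the target by random walks and, for each reference, extracts its ordered set
of non-overlapping, statistically significant alignments ("mappings") against
the target: align, test the z-score against the cut-off, record, remove the
alignment subnetwork from a working copy, repeat.  New references are added
until their combined coverage (all target nodes appearing in any stored
mapping's subnetwork) reaches eta percent of the target.  Step II reduces the
initial reference set to a final set with the same coverage guarantee by
greedy set cover (the classic ln-factor approximation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import random as _random
from dataclasses import dataclass, field
from typing import Sequence

from .alignment import Alignment, colorcode_align
from .network import Network, QueryTree, ScoringParams, SimilarityMatrix, ValidationError
from .significance import (
    DEFAULT_CUTOFF,
    DEFAULT_N_NULL,
    NullModelError,
    is_significant,
    sample_null_scores,
)

logger = logging.getLogger("netquery")

__all__ = [
    "ReferenceNetwork",
    "Mapping",
    "MappingSet",
    "ReferenceIndex",
    "StaleIndexError",
    "BuildError",
    "DEFAULT_K",
    "DEFAULT_ETA",
    "MAX_INITIAL_REFERENCES",
    "network_checksum",
    "sample_reference",
    "extract_mappings",
    "build_initial_set",
    "select_final_set",
    "build_index",
    "save_index",
    "load_index",
]

#: reference size: six nodes, matching the usual query size
DEFAULT_K = 6
#: coverage goal, percent of target nodes (studied range 60-80)
DEFAULT_ETA = 70.0
#: hard cap on the initial reference set (the growth loop has no natural
#: failure branch when eta is unreachable)
MAX_INITIAL_REFERENCES = 500


class StaleIndexError(RuntimeError):
    """Index checksum does not match the supplied target network."""


class BuildError(RuntimeError):
    """Index construction cannot proceed (e.g. target too small)."""


@dataclass(frozen=True)
class ReferenceNetwork:
    """A k-node subtree of the target, grown by a random walk."""

    ref_id: str
    tree: QueryTree  # node IDs are target node IDs
    seed: int

    def validate_against(self, t: Network) -> None:
        if not self.tree.nodes <= t.nodes:
            raise ValidationError(f"reference {self.ref_id} has nodes outside the target")
        for (u, v) in self.tree.edges:
            if not t.has_edge(u, v):
                raise ValidationError(f"reference {self.ref_id} edge ({u},{v}) not in target")


@dataclass(frozen=True)
class Mapping:
    """One stored alignment of a reference with the target."""

    phi: dict[str, str | None]  # reference node -> target node, None = deleted
    inserted: tuple[str, ...]
    score: float
    z: float

    @property
    def subnetwork_nodes(self) -> frozenset[str]:
        return frozenset(v for v in self.phi.values() if v is not None) | frozenset(self.inserted)


@dataclass(frozen=True)
class MappingSet:
    """Ordered, pairwise node-disjoint significant mappings of one reference."""

    ref_id: str
    mappings: tuple[Mapping, ...]

    @property
    def cover(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.mappings:
            out |= m.subnetwork_nodes
        return frozenset(out)

    def validate(self, cutoff: float) -> None:
        seen: set[str] = set()
        for m in self.mappings:
            nodes = m.subnetwork_nodes
            if nodes & seen:
                raise ValidationError(f"mappings of {self.ref_id} overlap")
            seen |= nodes
            if m.z < cutoff:
                raise ValidationError(f"mapping of {self.ref_id} below cutoff ({m.z} < {cutoff})")


@dataclass
class ReferenceIndex:
    """Final reference set with stored mappings and build metadata."""

    target_checksum: str
    params: dict
    initial_size: int
    references: list[tuple[ReferenceNetwork, MappingSet]]
    cover_nodes: frozenset[str]
    coverage_met: bool = True

    @property
    def n_references(self) -> int:
        return len(self.references)


def network_checksum(t: Network) -> str:
    """Order-independent hash of the node set and the weighted edge set."""
    h = hashlib.sha256()
    for n in sorted(t.nodes):
        h.update(n.encode())
        h.update(b"\x00")
    for (u, v) in sorted(t.weight):
        h.update(f"{u}\x01{v}\x01{t.weight[(u, v)]!r}".encode())
        h.update(b"\x00")
    return h.hexdigest()


def sample_reference(t: Network, k: int = DEFAULT_K, seed: int = 0, ref_id: str | None = None) -> ReferenceNetwork:
    """Grow a k-node subtree of ``t`` by a random walk.

    Starting from a uniform random seed node, repeatedly pick a uniform
    random target edge incident to the current reference whose other endpoint
    is outside, and add it.  Stalled walks restart from a fresh seed node
    (bounded retries)."""
    if k < 1:
        raise ValidationError("reference size k must be >= 1")
    rng = _random.Random(seed)
    tnodes = sorted(t.nodes)
    if len(tnodes) < k:
        raise BuildError(f"target has {len(tnodes)} nodes, cannot sample a {k}-node reference")
    for _attempt in range(100):
        start = rng.choice(tnodes)
        nodes = {start}
        edges: list[tuple[str, str, float]] = []
        while len(nodes) < k:
            frontier = [
                (u, v)
                for u in sorted(nodes)
                for v in sorted(t.neighbors(u))
                if v not in nodes
            ]
            if not frontier:
                break
            u, v = rng.choice(frontier)
            edges.append((u, v, t.edge_weight(u, v)))
            nodes.add(v)
        if len(nodes) == k:
            tree = QueryTree(ref_id or f"ref-{seed}", nodes, edges)
            return ReferenceNetwork(tree.id, tree, seed)
    raise BuildError(f"no connected component of size >= {k} reachable by the walk")


def extract_mappings(
    r: ReferenceNetwork,
    t: Network,
    sim_rt: SimilarityMatrix,
    p: ScoringParams,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    n_null: int = DEFAULT_N_NULL,
) -> MappingSet:
    """Iteratively extract non-overlapping significant mappings of ``r`` in ``t``.

    Each round aligns the reference against the current (reduced) target,
    tests significance against a null sampled on the *original* target, and on
    success removes the alignment subnetwork from the working copy.  Stops at
    the first non-significant (or infeasible) alignment."""
    r.validate_against(t)
    try:
        null = sample_null_scores(r.tree, t, sim_rt, p, n_null=n_null, seed=seed)
    except NullModelError:
        return MappingSet(r.ref_id, ())
    working = t
    mappings: list[Mapping] = []
    round_no = 0
    while working.n_nodes >= 1:
        a = colorcode_align(r.tree, working, sim_rt, p, seed=seed + 1 + round_no)
        if a is None:
            break
        ok, z = is_significant(a, r.tree, t, sim_rt, p, cutoff=cutoff, null=null)
        if not ok:
            break
        phi: dict[str, str | None] = {u: a.matched.get(u) for u in r.tree.nodes}
        mappings.append(Mapping(phi, a.inserted_target, a.score, z))
        working = working.remove_nodes(a.subnetwork_nodes)
        round_no += 1
    return MappingSet(r.ref_id, tuple(mappings))


def build_initial_set(
    t: Network,
    sim_tt: SimilarityMatrix,
    p: ScoringParams,
    k: int = DEFAULT_K,
    eta: float = DEFAULT_ETA,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    n_null: int = DEFAULT_N_NULL,
    max_references: int = MAX_INITIAL_REFERENCES,
) -> tuple[list[tuple[ReferenceNetwork, MappingSet]], bool]:
    """Step I: sample references until coverage reaches eta % of the target.

    Returns (initial set, eta_reached).  Stops early (with a warning) at
    ``max_references``."""
    if not (0 < eta <= 100):
        raise ValidationError("eta must be in (0, 100]")
    goal = eta / 100.0 * t.n_nodes
    initial: list[tuple[ReferenceNetwork, MappingSet]] = []
    covered: set[str] = set()
    i = 0
    while len(covered) < goal and i < max_references:
        ref = sample_reference(t, k=k, seed=seed + 10_000 * i, ref_id=f"R{i}")
        mset = extract_mappings(ref, t, sim_tt, p, cutoff=cutoff, seed=seed + 10_000 * i + 1, n_null=n_null)
        initial.append((ref, mset))
        covered |= mset.cover
        i += 1
    reached = len(covered) >= goal
    if not reached:
        logger.warning(
            "initial set capped at %d references with %.1f%% coverage (< eta = %.1f%%)",
            len(initial), 100.0 * len(covered) / max(t.n_nodes, 1), eta,
        )
    return initial, reached


def select_final_set(
    initial: Sequence[tuple[ReferenceNetwork, MappingSet]],
    eta: float,
    n_target_nodes: int,
) -> list[tuple[ReferenceNetwork, MappingSet]]:
    """Step II: greedy set cover down to the smallest reference subset whose
    coverage still reaches eta % of the target (ties broken by creation
    order).  If the initial coverage falls short, returns everything with a
    warning."""
    goal = eta / 100.0 * n_target_nodes
    total_cover: set[str] = set()
    for _, mset in initial:
        total_cover |= mset.cover
    if len(total_cover) < goal:
        logger.warning("initial coverage below eta; keeping all %d references", len(initial))
        return list(initial)
    chosen: list[tuple[ReferenceNetwork, MappingSet]] = []
    covered: set[str] = set()
    remaining = list(initial)
    while len(covered) < goal:
        best_i, best_gain = 0, -1
        for i, (_, mset) in enumerate(remaining):
            gain = len(mset.cover - covered)
            if gain > best_gain:  # strict: earlier creation order wins ties
                best_i, best_gain = i, gain
        ref = remaining.pop(best_i)
        chosen.append(ref)
        covered |= ref[1].cover
    return chosen


def build_index(
    t: Network,
    sim_tt: SimilarityMatrix,
    p: ScoringParams,
    k: int = DEFAULT_K,
    eta: float = DEFAULT_ETA,
    cutoff: float = DEFAULT_CUTOFF,
    seed: int = 0,
    n_null: int = DEFAULT_N_NULL,
    max_references: int = MAX_INITIAL_REFERENCES,
) -> ReferenceIndex:
    """Full two-step index construction over target ``t``."""
    initial, reached = build_initial_set(
        t, sim_tt, p, k=k, eta=eta, cutoff=cutoff, seed=seed, n_null=n_null,
        max_references=max_references,
    )
    final = select_final_set(initial, eta, t.n_nodes)
    cover: set[str] = set()
    for _, mset in final:
        cover |= mset.cover
    return ReferenceIndex(
        target_checksum=network_checksum(t),
        params={
            "k": k,
            "eta": eta,
            "cutoff": cutoff,
            "confidence": p.confidence,
            "delta_ins": p.delta_ins,
            "delta_del": p.delta_del,
            "max_ins": p.max_ins,
            "max_del": p.max_del,
            "count_bridge_weights": p.count_bridge_weights,
            "n_null": n_null,
            "seed": seed,
        },
        initial_size=len(initial),
        references=final,
        cover_nodes=frozenset(cover),
        coverage_met=reached,
    )


# ---------------------------------------------------------------------------
# JSON (de)serialization


def _index_to_dict(ix: ReferenceIndex) -> dict:
    return {
        "format": "netquery-index/1",
        "target_checksum": ix.target_checksum,
        "params": ix.params,
        "initial_size": ix.initial_size,
        "coverage_met": ix.coverage_met,
        "cover_nodes": sorted(ix.cover_nodes),
        "references": [
            {
                "ref_id": ref.ref_id,
                "seed": ref.seed,
                "nodes": sorted(ref.tree.nodes),
                "edges": [[u, v, ref.tree.weight[(u, v)]] for (u, v) in sorted(ref.tree.edges)],
                "mappings": [
                    {
                        "phi": [[u, m.phi[u]] for u in sorted(m.phi)],
                        "inserted": list(m.inserted),
                        "score": m.score,
                        "z": m.z,
                    }
                    for m in mset.mappings
                ],
            }
            for ref, mset in ix.references
        ],
    }


def save_index(ix: ReferenceIndex, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(_index_to_dict(ix), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_index(path, t: Network) -> ReferenceIndex:
    """Load an index and verify it was built for ``t`` (checksum match)."""
    with open(path, "rt", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed index JSON: {exc}") from exc
    checksum = network_checksum(t)
    if data.get("target_checksum") != checksum:
        raise StaleIndexError(
            "index was built for a different target network (checksum mismatch)"
        )
    references = []
    for rec in data["references"]:
        tree = QueryTree(rec["ref_id"], rec["nodes"], [tuple(e) for e in rec["edges"]])
        ref = ReferenceNetwork(rec["ref_id"], tree, rec["seed"])
        mappings = tuple(
            Mapping(
                phi={u: v for u, v in m["phi"]},
                inserted=tuple(m["inserted"]),
                score=float(m["score"]),
                z=float(m["z"]),
            )
            for m in rec["mappings"]
        )
        references.append((ref, MappingSet(rec["ref_id"], mappings)))
    return ReferenceIndex(
        target_checksum=data["target_checksum"],
        params=data["params"],
        initial_size=int(data["initial_size"]),
        references=references,
        cover_nodes=frozenset(data["cover_nodes"]),
        coverage_met=bool(data.get("coverage_met", True)),
    )
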