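"""Index-accelerated query processing.

Given a query tree and a pre-built reference index over the target: align the
query against each reference (cheap: both are small); for references scoring
above a threshold, compose the query-to-reference alignment psi with each of
the reference's stored target mappings phi into an *indirect* mapping
phi(psi(.)) that forces a subset S of query nodes onto target nodes S'.  For
each candidate, a topology-free upper bound (maximum-weight bipartite
matching of similarities plus an edge-weight allowance) prunes hopeless
candidates; survivors are refined by an *induced* alignment — the color-coding
engine constrained to respect the forced pairs, with as many colors as there
are unmapped query nodes (plus the insertion budget).  The best induced
alignment over all candidates is returned with its z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import linear_sum_assignment

from .alignment import Alignment, colorcode_align
from .index import Mapping, ReferenceIndex, ReferenceNetwork, StaleIndexError, network_checksum
from .network import Network, QueryTree, ScoringParams, SimilarityMatrix, ValidationError
from .significance import DEFAULT_N_NULL, NullModelError, sample_null_scores, z_score

logger = logging.getLogger("netquery")

__all__ = [
    "IndirectMapping",
    "QueryResult",
    "DEFAULT_THETA",
    "align_to_reference",
    "compose_indirect",
    "upper_bound",
    "induced_align",
    "query_index",
]

#: reference-screening threshold as a fraction of the ideal query/reference score
DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class IndirectMapping:
    """Forced query-to-target pairs obtained by composing psi and phi."""

    forced: dict[str, str]
    free_query: frozenset[str]
    ref_id: str
    mapping_index: int

    @property
    def S(self) -> frozenset[str]:
        return frozenset(self.forced)

    @property
    def S_prime(self) -> frozenset[str]:
        return frozenset(self.forced.values())


@dataclass
class CandidateRecord:
    """Per-candidate trace of the query loop (for reporting and testing)."""

    ref_id: str
    mapping_index: int
    outcome: str  # "screened" | "bound-pruned" | "examined"
    upper_bound: float | None = None
    induced_score: float | None = None


@dataclass
class QueryResult:
    best: Alignment | None
    z: float | None
    pruned_by_screen: int
    pruned_by_bound: int
    examined: int
    candidates: list[CandidateRecord] = field(default_factory=list)
    best_ref_id: str | None = None
    best_mapping_index: int | None = None

    @property
    def total_candidates(self) -> int:
        return self.pruned_by_screen + self.pruned_by_bound + self.examined


def ideal_score(q: QueryTree, r: ReferenceNetwork, sim_qr: SimilarityMatrix) -> float:
    """Best conceivable query/reference score: every query node at its most
    similar reference node, every query edge on the heaviest reference edge."""
    total = 0.0
    rnodes = sorted(r.tree.nodes)
    for u in sorted(q.nodes):
        total += max((sim_qr.get(u, w) for w in rnodes), default=0.0)
    max_w = max(r.tree.weight.values(), default=0.0)
    total += q.n_edges * max_w
    return total


def align_to_reference(
    q: QueryTree,
    r: ReferenceNetwork,
    sim_qr: SimilarityMatrix,
    p: ScoringParams,
    theta: float = DEFAULT_THETA,
    threshold: float | None = None,
    seed: int = 0,
) -> Alignment | None:
    """Align the query to one reference; reject (None) below the threshold.

    The default threshold is ``theta`` times the ideal query/reference score.
    An alignment whose node-similarity contribution is zero is always
    rejected: a reference with no homologous nodes cannot represent the
    query, no matter how well the topologies happen to match.
    """
    if threshold is None:
        threshold = theta * ideal_score(q, r, sim_qr)
    psi = colorcode_align(q, r.tree, sim_qr, p, seed=seed)
    if psi is None or psi.score < threshold:
        return None
    if sum(sim_qr.get(u, w) for u, w in psi.matched.items()) == 0.0:
        return None
    return psi


def compose_indirect(
    psi: Alignment,
    phi: Mapping,
    q: QueryTree,
    ref_id: str,
    mapping_index: int,
    sim: SimilarityMatrix | None = None,
) -> IndirectMapping:
    """Compose psi (query -> reference) with phi (reference -> target).

    A query node u is forced iff psi matches it to a reference node w, phi(w)
    is not deleted, and — when a query/target similarity is supplied — the
    composed pair has positive similarity.  The similarity condition keeps S
    restricted to homology-supported pairs: a composed pair without any
    sequence evidence is left free for the induced alignment to place, which
    matters when similarities are sparse (most protein pairs have no BLAST
    hit at all)."""
    forced: dict[str, str] = {}
    for u, w in psi.matched.items():
        v = phi.phi.get(w)
        if v is not None and (sim is None or sim.get(u, v) > 0.0):
            forced[u] = v
    free = frozenset(q.nodes) - set(forced)
    return IndirectMapping(forced=forced, free_query=free, ref_id=ref_id, mapping_index=mapping_index)


def upper_bound(
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    im: IndirectMapping,
    p: ScoringParams | None = None,
) -> float:
    """Topology-free upper bound on any induced alignment respecting ``im``.

    Node part: forced pairs contribute their similarity; free query nodes are
    assigned to targets outside S' by maximum-weight bipartite matching
    (Hungarian method on the similarity matrix).  Edge part: the topology
    constraint is dropped, so each query edge is granted the heaviest target
    edge weight (times the maximal bridging-path length when bridging-path
    weights are counted).  Indel penalties are nonpositive and dropped.
    """
    total = sum(sim.get(u, v) for u, v in im.forced.items())
    free = sorted(im.free_query)
    cols = sorted(t.nodes - im.S_prime)
    if free and cols:
        mat = np.zeros((len(free), len(cols)))
        for i, u in enumerate(free):
            for j, v in enumerate(cols):
                mat[i, j] = sim.get(u, v)
        if len(free) <= len(cols):
            ri, ci = linear_sum_assignment(mat, maximize=True)
            total += float(mat[ri, ci].sum())
        else:
            # more free query nodes than available targets: pad with zero columns
            pad = np.zeros((len(free), len(free) - len(cols)))
            ri, ci = linear_sum_assignment(np.hstack([mat, pad]), maximize=True)
            total += float(np.hstack([mat, pad])[ri, ci].sum())
    max_w = max(t.weight.values(), default=0.0)
    per_edge = max_w
    if p is not None and p.count_bridge_weights:
        per_edge = max_w * (1 + p.max_ins)
    total += q.n_edges * per_edge
    return total


def induced_align(
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    im: IndirectMapping,
    p: ScoringParams,
    seed: int = 0,
) -> Alignment | None:
    """Constrained alignment respecting the indirect mapping's forced pairs.

    Runs the color-coding engine with the forced pairs fixed: forced target
    nodes take no color, are never insertion sites, and never match other
    query nodes; the color count shrinks to the number of free query nodes
    plus the insertion budget."""
    return colorcode_align(q, t, sim, p, forced=im.forced, seed=seed)


def sim_query_to_reference(sim_qt: SimilarityMatrix, r: ReferenceNetwork) -> SimilarityMatrix:
    """Query/reference similarity, reading reference nodes as target nodes."""
    return sim_qt.restrict(t_nodes=r.tree.nodes)


def query_index(
    q: QueryTree,
    t: Network,
    ix: ReferenceIndex,
    sim_qt: SimilarityMatrix,
    p: ScoringParams,
    theta: float = DEFAULT_THETA,
    seed: int = 0,
    n_null: int = DEFAULT_N_NULL,
    prune: bool = True,
    compute_z: bool = True,
) -> QueryResult:
    """Process a query against the index (the full Algorithm-2 loop).

    References are screened by their query alignment score and processed in
    descending score order; stored mappings whose upper bound cannot beat the
    current best are skipped (unless ``prune`` is False).  Returns the best
    induced alignment with pruning counters and its z-score.
    """
    if network_checksum(t) != ix.target_checksum:
        raise StaleIndexError("index does not match the supplied target network")
    result = QueryResult(best=None, z=None, pruned_by_screen=0, pruned_by_bound=0, examined=0)
    screened: list[tuple[float, int, ReferenceNetwork, object, Alignment]] = []
    for ri, (ref, mset) in enumerate(ix.references):
        sim_qr = sim_query_to_reference(sim_qt, ref)
        psi = align_to_reference(q, ref, sim_qr, p, theta=theta, seed=seed + 101 * ri)
        if psi is None:
            result.pruned_by_screen += len(mset.mappings)
            for mi in range(len(mset.mappings)):
                result.candidates.append(CandidateRecord(ref.ref_id, mi, "screened"))
            continue
        screened.append((psi.score, ri, ref, mset, psi))
    screened.sort(key=lambda rec: (-rec[0], rec[1]))

    best_score = -np.inf
    for _, ri, ref, mset, psi in screened:
        for mi, phi in enumerate(mset.mappings):
            im = compose_indirect(psi, phi, q, ref.ref_id, mi, sim=sim_qt)
            ub = upper_bound(q, t, sim_qt, im, p)
            if prune and ub <= best_score:
                result.pruned_by_bound += 1
                result.candidates.append(CandidateRecord(ref.ref_id, mi, "bound-pruned", upper_bound=ub))
                continue
            a = induced_align(q, t, sim_qt, im, p, seed=seed + 1009 * ri + 31 * mi)
            result.examined += 1
            result.candidates.append(
                CandidateRecord(
                    ref.ref_id, mi, "examined", upper_bound=ub,
                    induced_score=(a.score if a else None),
                )
            )
            if a is not None and a.score > best_score:
                best_score = a.score
                result.best = a
                result.best_ref_id = ref.ref_id
                result.best_mapping_index = mi
    if result.best is not None and compute_z:
        try:
            null = sample_null_scores(q, t, sim_qt, p, n_null=n_null, seed=seed + 777)
            result.z = z_score(result.best.score, null) if null.sd > 0 else float("inf")
        except NullModelError:
            result.z = None
    return result
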