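"""Synthetic instance generation.

Emulates the experimental constructions used to study reference-based network
querying: random connected targets (Erdos-Renyi or preferential attachment,
with densities in the range of real PPI networks, e.g. E. coli's 4.7
interactions per protein), query trees sampled from the target by random
walks, topology perturbations (leaf insertion, edge splitting, node
deletion), homology perturbation (amino-acid point mutation of node
sequences, or a sequence-free similarity decay), and planted motifs with
ground-truth sites for recovery tests.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .index import BuildError, sample_reference
from .network import Network, QueryTree, SimilarityMatrix, ValidationError

__all__ = [
    "AMINO_ACIDS",
    "ECOLI_DENSITY",
    "SyntheticInstance",
    "generate_target",
    "sample_query",
    "perturb_topology",
    "mutate_sequences",
    "random_sequences",
    "sequence_identity_similarity",
    "perturb_similarity",
    "identity_similarity",
    "plant_motif",
    "plant_copies",
    "random_instance",
    "generate_instance",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: average interactions per protein of the densest real target studied (E. coli)
ECOLI_DENSITY = 4.7

#: background similarity range for non-homologous pairs
BACKGROUND_MAX = 0.1


def generate_target(
    n_nodes: int,
    model: str = "preferential_attachment",
    density: float = ECOLI_DENSITY,
    seed: int = 0,
) -> Network:
    """Random connected target network with ~``density`` interactions per node.

    The largest connected component is kept (its size is logged by the graph
    being returned with fewer nodes than requested); edge weights are uniform
    in [0.5, 1]."""
    if n_nodes < 2:
        raise ValidationError("target needs at least 2 nodes")
    rng = _random.Random(seed)
    if model in ("erdos_renyi", "er"):
        p = density / (n_nodes - 1)
        if not (0 < p <= 1):
            raise ValidationError(f"density {density} unreachable with {n_nodes} nodes")
        g = nx.gnp_random_graph(n_nodes, p, seed=rng.randrange(2**31))
    elif model in ("preferential_attachment", "pa"):
        m = max(1, round(density / 2))
        if m >= n_nodes:
            raise ValidationError(f"density {density} unreachable with {n_nodes} nodes")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=rng.randrange(2**31))
    else:
        raise ValidationError(f"unknown target model {model!r}")
    largest = max(nx.connected_components(g), key=len)
    g = g.subgraph(largest)
    width = len(str(n_nodes))
    name = {i: f"t{i:0{width}d}" for i in g.nodes}
    edges = [(name[u], name[v], round(rng.uniform(0.5, 1.0), 6)) for u, v in sorted(g.edges)]
    return Network(f"synthetic-{model}-{seed}", set(name[i] for i in g.nodes), edges)


def sample_query(t: Network, m: int = 6, seed: int = 0, query_id: str | None = None) -> QueryTree:
    """An m-node query tree sampled from the target by random walk (the query
    is a subtree of the target and keeps the target node identifiers)."""
    ref = sample_reference(t, k=m, seed=seed, ref_id=query_id or f"query-{seed}")
    return ref.tree


def perturb_topology(q: QueryTree, op: str, seed: int = 0) -> QueryTree:
    """Apply one topology edit; the result is always a tree.

    insert_leaf: attach a new node to a random node.
    split_edge: replace a random edge (u, v) by (u, w), (w, v).
    delete_node: remove a random degree-1 node (with its edge) or degree-2
        node (reconnecting its neighbors).  New edges weigh 1.0.
    """
    rng = _random.Random(seed)
    nodes = sorted(q.nodes)
    fresh = "w0"
    k = 0
    while fresh in q.nodes:
        k += 1
        fresh = f"w{k}"
    if op == "insert_leaf":
        anchor = rng.choice(nodes)
        edges = [(u, v, q.weight[(u, v)]) for (u, v) in q.edges] + [(anchor, fresh, 1.0)]
        return QueryTree(f"{q.id}+leaf", set(nodes) | {fresh}, edges)
    if op == "split_edge":
        if q.n_edges == 0:
            raise ValidationError("cannot split an edge of a single-node tree")
        u, v = rng.choice(sorted(q.edges))
        edges = [(a, b, q.weight[(a, b)]) for (a, b) in q.edges if (a, b) != (u, v)]
        edges += [(u, fresh, 1.0), (fresh, v, 1.0)]
        return QueryTree(f"{q.id}+split", set(nodes) | {fresh}, edges)
    if op == "delete_node":
        candidates = [n for n in nodes if len(q.neighbors(n)) in (1, 2)]
        if q.n_nodes == 1 or not candidates:
            raise ValidationError("no degree-1 or degree-2 node to delete")
        w = rng.choice(candidates)
        nb = sorted(q.neighbors(w))
        edges = [(a, b, q.weight[(a, b)]) for (a, b) in q.edges if w not in (a, b)]
        if len(nb) == 2:
            edges.append((nb[0], nb[1], 1.0))
        return QueryTree(f"{q.id}-node", set(nodes) - {w}, edges)
    raise ValidationError(f"unknown topology operation {op!r}")


def random_sequences(nodes: Iterable[str], length: int = 300, seed: int = 0) -> dict[str, str]:
    """Random amino-acid sequences, one per node."""
    rng = _random.Random(seed)
    return {n: "".join(rng.choice(AMINO_ACIDS) for _ in range(length)) for n in sorted(nodes)}


def mutate_sequences(seqs: Mapping[str, str], mu_percent: float, seed: int = 0) -> dict[str, str]:
    """Point-mutate each residue independently with probability mu_percent/100,
    replacing it by a uniform choice among the 19 other amino acids."""
    if not (0 <= mu_percent <= 100):
        raise ValidationError("mu_percent must be in [0, 100]")
    rng = _random.Random(seed)
    prob = mu_percent / 100.0
    out: dict[str, str] = {}
    for n in sorted(seqs):
        s = seqs[n]
        bad = set(s) - set(AMINO_ACIDS)
        if bad:
            raise ValidationError(f"sequence of {n!r} has non-amino-acid letters {sorted(bad)}")
        chars = []
        for ch in s:
            if prob > 0 and rng.random() < prob:
                choices = AMINO_ACIDS.replace(ch, "")
                chars.append(rng.choice(choices))
            else:
                chars.append(ch)
        out[n] = "".join(chars)
    return out


def sequence_identity_similarity(
    q_seqs: Mapping[str, str], t_seqs: Mapping[str, str]
) -> SimilarityMatrix:
    """Position-wise identity fraction (matches / longer length) as similarity."""
    sim = SimilarityMatrix()
    for u, su in q_seqs.items():
        for v, sv in t_seqs.items():
            matches = sum(1 for a, b in zip(su, sv) if a == b)
            denom = max(len(su), len(sv))
            if denom:
                sim.set(u, v, matches / denom)
    return sim


def perturb_similarity(sim: SimilarityMatrix, mu_percent: float, seed: int = 0) -> SimilarityMatrix:
    """Sequence-free surrogate for homology perturbation: each entry decays
    toward a random background level, sim' = sim (1 - mu/100) + b mu/100 with
    b uniform in [0, 0.1]."""
    if not (0 <= mu_percent <= 100):
        raise ValidationError("mu_percent must be in [0, 100]")
    rng = _random.Random(seed)
    frac = mu_percent / 100.0
    out = SimilarityMatrix()
    for (u, v) in sorted(dict(sim.items())):
        background = rng.uniform(0.0, BACKGROUND_MAX)
        out.set(u, v, sim.get(u, v) * (1 - frac) + background * frac)
    return out


def identity_similarity(t: Network, self_sim: float = 1.0) -> SimilarityMatrix:
    """Within-network similarity: each node maximally similar to itself.
    Used when aligning references (drawn from the target) back to the target."""
    sim = SimilarityMatrix()
    for v in t.nodes:
        sim.set(v, v, self_sim)
    return sim


def plant_copies(
    t: Network,
    motif: QueryTree,
    n_copies: int,
    seed: int = 0,
    background_rate: float = 0.25,
) -> tuple[Network, SimilarityMatrix, list[dict[str, str]]]:
    """Plant ``n_copies`` node-disjoint copies of ``motif`` in the target.

    Each copy occupies a random-walk site of |motif| currently unused nodes;
    missing edges between site images of motif-adjacent nodes are added with
    random weights in [0.5, 1].  The returned similarity has 1.0 on
    (motif node, its image) pairs; a ``background_rate`` fraction of the
    remaining pairs get spurious background similarity uniform in (0, 0.1]
    and the rest have none — mirroring sparse sequence-search hits.  The
    third element lists each copy's motif-to-site map.
    """
    rng = _random.Random(seed)
    if motif.n_nodes * n_copies > t.n_nodes:
        raise BuildError("no room to plant the requested copies")
    used: set[str] = set()
    sites: list[dict[str, str]] = []
    working_edges = dict(t.weight)
    for c in range(n_copies):
        available = t.nodes - used
        sub = t.subnetwork(available)
        site_tree = sample_reference(sub, k=motif.n_nodes, seed=seed + 7919 * (c + 1)).tree
        site_nodes = sorted(site_tree.nodes)
        mnodes = sorted(motif.nodes)
        perm = rng.sample(site_nodes, len(site_nodes))
        mapping = dict(zip(mnodes, perm))
        for (a, b) in sorted(motif.edges):  # fixed order keeps rng draws reproducible
            ia, ib = mapping[a], mapping[b]
            key = (ia, ib) if ia <= ib else (ib, ia)
            if key not in working_edges:
                working_edges[key] = round(rng.uniform(0.5, 1.0), 6)
        used |= set(site_nodes)
        sites.append(mapping)
    t2 = Network(f"{t.id}+planted", t.nodes, working_edges)
    sim = SimilarityMatrix()
    planted_pairs = {(u, m[u]) for m in sites for u in m}
    for u in sorted(motif.nodes):
        for v in sorted(t2.nodes):
            if (u, v) in planted_pairs:
                sim.set(u, v, 1.0)
            elif rng.random() < background_rate:
                sim.set(u, v, round(rng.uniform(0.01, BACKGROUND_MAX), 6))
    return t2, sim, sites


def plant_motif(
    t: Network, q: QueryTree, seed: int = 0
) -> tuple[Network, SimilarityMatrix, dict[str, str]]:
    """Plant one copy of ``q`` in the target; returns (target', sim, site map)."""
    if q.n_nodes >= t.n_nodes:
        raise BuildError("query must be smaller than the target")
    t2, sim, sites = plant_copies(t, q, 1, seed=seed)
    return t2, sim, sites[0]


def random_instance(
    seed: int,
    n_target: tuple[int, int] = (8, 12),
    n_query: tuple[int, int] = (3, 5),
    edge_prob: float = 0.3,
) -> tuple[QueryTree, Network, SimilarityMatrix]:
    """A small random (query tree, target, dense uniform similarity) triple.

    Target: connected G(n, p) with weights uniform in [0.5, 1]; query: a
    uniform random labeled tree; similarities: uniform in [0, 1] on every
    query-target pair.  Sized for exhaustive verification."""
    rng = _random.Random(seed)
    nt = rng.randint(*n_target)
    g = nx.gnp_random_graph(nt, edge_prob, seed=rng.randrange(2**31))
    while not nx.is_connected(g):
        g = nx.gnp_random_graph(nt, edge_prob, seed=rng.randrange(2**31))
    target = Network(
        f"rand-target-{seed}",
        [f"t{i}" for i in g.nodes],
        [(f"t{u}", f"t{v}", round(rng.uniform(0.5, 1.0), 6)) for u, v in sorted(g.edges)],
    )
    nq = rng.randint(*n_query)
    tr = nx.random_labeled_tree(nq, seed=rng.randrange(2**31))
    query = QueryTree(
        f"rand-query-{seed}",
        [f"q{i}" for i in tr.nodes],
        [(f"q{u}", f"q{v}", 1.0) for u, v in sorted(tr.edges)],
    )
    sim = SimilarityMatrix()
    for u in sorted(query.nodes):
        for v in sorted(target.nodes):
            sim.set(u, v, round(rng.uniform(0.0, 1.0), 6))
    return query, target, sim


@dataclass(frozen=True)
class SyntheticInstance:
    """A complete generated fixture: target, queries, similarities, truth.

    ``sim_qt`` holds one query-to-target similarity per query id, because the
    homology perturbation level differs between query variants."""

    target: Network
    queries: tuple[QueryTree, ...]
    sim_tt: SimilarityMatrix
    sim_qt: dict[str, SimilarityMatrix]
    planted: dict[str, frozenset[str]]  # query id -> ground-truth site nodes
    seed: int
    config: dict = field(default_factory=dict)


def generate_instance(
    n_nodes: int = 100,
    model: str = "preferential_attachment",
    density: float = 2.4,
    n_queries: int = 3,
    m: int = 6,
    topology_ops: Sequence[str] = ("insert_leaf", "delete_node"),
    mu_values: Sequence[float] = (0.0, 5.0, 10.0, 20.0),
    seed: int = 0,
) -> SyntheticInstance:
    """Target + query-set bundle mirroring the perturbation study design:
    per base query, one variant per topology op and per mutation level
    (base topology x mu levels included), with ground-truth sites for the
    unperturbed queries."""
    target = generate_target(n_nodes, model=model, density=density, seed=seed)
    sim_tt = identity_similarity(target)
    queries: list[QueryTree] = []
    planted: dict[str, frozenset[str]] = {}
    sim_qt: dict[str, SimilarityMatrix] = {}
    rng = _random.Random(seed + 1)
    for qi in range(n_queries):
        base = sample_query(target, m=m, seed=seed + 31 * (qi + 1), query_id=f"q{qi}")
        variants: list[QueryTree] = [base]
        for oi, op in enumerate(topology_ops):
            variants.append(perturb_topology(base, op, seed=seed + 97 * (qi + 1) + 13 * oi))
        for variant in variants:
            for mu in mu_values:
                vid = f"{variant.id}|mu{mu:g}"
                qv = QueryTree(vid, variant.nodes, variant.weight)
                queries.append(qv)
                planted[vid] = frozenset(n for n in qv.nodes if n in target.nodes)
                base_sim = SimilarityMatrix()
                for u in qv.nodes:
                    if u in target.nodes:
                        base_sim.set(u, u, 1.0)
                sim_qt[vid] = perturb_similarity(base_sim, mu, seed=rng.randrange(2**31))
    return SyntheticInstance(
        target=target,
        queries=tuple(queries),
        sim_tt=sim_tt,
        sim_qt=sim_qt,
        planted=planted,
        seed=seed,
        config={
            "n_nodes": n_nodes,
            "model": model,
            "density": density,
            "n_queries": n_queries,
            "m": m,
            "topology_ops": list(topology_ops),
            "mu_values": list(mu_values),
        },
    )
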