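"""Domain types and flat-file I/O for networks and node similarities.

Networks are undirected, weighted graphs of protein identifiers with edge
weights (interaction confidences) in [0, 1].  Query and reference networks
are trees.  Node-node similarity is a sparse nonnegative map in [0, 1],
typically derived from sequence homology (normalized negative log E-values).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("netquery")

__all__ = [
    "Network",
    "QueryTree",
    "SimilarityMatrix",
    "ScoringParams",
    "NetworkFormatError",
    "ValidationError",
    "read_network",
    "write_network",
    "read_query",
    "read_similarity",
    "write_similarity",
    "similarity_from_evalues",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class NetworkFormatError(ValidationError):
    """Raised on a malformed network or similarity file."""


def _edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical (sorted) form of an undirected edge."""
    return (u, v) if u <= v else (v, u)


class Network:
    """An undirected, weighted network of named nodes.

    Invariants enforced at construction: no self-loops, no duplicate edges
    (undirected), every edge endpoint declared as a node, weights in [0, 1].
    """

    def __init__(
        self,
        id: str,
        nodes: Iterable[str],
        edges: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = (),
    ) -> None:
        self.id = str(id)
        node_set = {str(n) for n in nodes}
        if isinstance(edges, Mapping):
            edge_items = [(u, v, w) for (u, v), w in edges.items()]
        else:
            edge_items = list(edges)
        weight: dict[tuple[str, str], float] = {}
        for u, v, w in edge_items:
            u, v, w = str(u), str(v), float(w)
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u!r}, {v!r}) references an undeclared node")
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"edge ({u!r}, {v!r}) weight {w} outside [0, 1]")
            key = _edge_key(u, v)
            if key in weight:
                raise ValidationError(f"duplicate edge ({u!r}, {v!r})")
            weight[key] = w
        self.nodes: frozenset[str] = frozenset(node_set)
        self.weight: dict[tuple[str, str], float] = weight

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.weight)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weight)

    def has_edge(self, u: str, v: str) -> bool:
        return _edge_key(u, v) in self.weight

    def edge_weight(self, u: str, v: str, default: float | None = None) -> float:
        key = _edge_key(u, v)
        if key in self.weight:
            return self.weight[key]
        if default is not None:
            return default
        raise KeyError(f"no edge ({u!r}, {v!r}) in network {self.id!r}")

    def neighbors(self, u: str) -> set[str]:
        return {b if a == u else a for (a, b) in self.weight if u in (a, b)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(id=self.id)
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in self.weight.items():
            g.add_edge(u, v, weight=w)
        return g

    def subnetwork(self, nodes: Iterable[str], id: str | None = None) -> "Network":
        """Induced subnetwork on ``nodes``."""
        keep = set(nodes)
        missing = keep - self.nodes
        if missing:
            raise ValidationError(f"nodes not in network: {sorted(missing)}")
        edges = {k: w for k, w in self.weight.items() if k[0] in keep and k[1] in keep}
        return Network(id or f"{self.id}|sub", keep, edges)

    def remove_nodes(self, nodes: Iterable[str], id: str | None = None) -> "Network":
        drop = set(nodes)
        return self.subnetwork(self.nodes - drop, id=id or self.id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.nodes == other.nodes and self.weight == other.weight

    def __hash__(self) -> int:
        return hash((self.nodes, frozenset(self.weight.items())))

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.id!r}: {self.n_nodes} nodes, {self.n_edges} edges>"


class QueryTree(Network):
    """A network that is a tree: connected, acyclic, at least one node."""

    def __init__(self, id, nodes, edges=()) -> None:
        super().__init__(id, nodes, edges)
        if self.n_nodes < 1:
            raise ValidationError("a query tree needs at least one node")
        if self.n_edges != self.n_nodes - 1 or not nx.is_connected(self.to_networkx()):
            raise ValidationError(f"query {self.id!r} is not a tree (connected, |E| = |V| - 1)")


class SimilarityMatrix:
    """Sparse query-side x target-side node similarity; absent pairs are 0."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None) -> None:
        self._entries: dict[tuple[str, str], float] = {}
        if entries:
            for (q, t), s in entries.items():
                self.set(q, t, s)

    def set(self, q: str, t: str, s: float) -> None:
        s = float(s)
        if not (0.0 <= s <= 1.0):
            raise ValidationError(f"similarity sim({q!r}, {t!r}) = {s} outside [0, 1]")
        self._entries[(str(q), str(t))] = s

    def get(self, q: str, t: str) -> float:
        return self._entries.get((q, t), 0.0)

    def items(self):
        return self._entries.items()

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return self._entries == other._entries

    def restrict(self, q_nodes: Iterable[str] | None = None, t_nodes: Iterable[str] | None = None) -> "SimilarityMatrix":
        qs = set(q_nodes) if q_nodes is not None else None
        ts = set(t_nodes) if t_nodes is not None else None
        out = SimilarityMatrix()
        for (q, t), s in self._entries.items():
            if (qs is None or q in qs) and (ts is None or t in ts):
                out._entries[(q, t)] = s
        return out

    def relabel_query(self, mapping: Mapping[str, str]) -> "SimilarityMatrix":
        """Rename query-side nodes; pairs whose query node is absent are dropped."""
        out = SimilarityMatrix()
        for (q, t), s in self._entries.items():
            if q in mapping:
                out._entries[(mapping[q], t)] = s
        return out


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring knobs.

    delta_ins / delta_del: nonpositive per-indel penalties.
    max_ins / max_del: indel budget (at most two each, the usual setting).
    confidence: probability with which the color-coding search returns the
        constrained optimum (determines the number of random-coloring trials).
    count_bridge_weights: when True, the weights of the edges along a bridging
        target path (a query edge realized across inserted nodes) are added to
        the score; when False (default) the score is exactly the classic
        formula: matched similarities + directly aligned edge weights +
        indel penalties.
    """

    delta_ins: float = -0.5
    delta_del: float = -0.5
    max_ins: int = 2
    max_del: int = 2
    confidence: float = 0.99
    count_bridge_weights: bool = False

    def __post_init__(self) -> None:
        if self.delta_ins > 0 or self.delta_del > 0:
            raise ValidationError("indel penalties must be <= 0")
        if self.max_ins < 0 or self.max_del < 0:
            raise ValidationError("indel caps must be >= 0")
        if not (0.0 < self.confidence < 1.0):
            raise ValidationError("confidence must be in (0, 1)")


# ---------------------------------------------------------------------------
# Flat-file I/O


def read_network(path, id: str = "network") -> Network:
    """Read an edge-list TSV: ``u<TAB>v[<TAB>w]`` per line, weight default 1.0.

    Self-loops and duplicate (undirected) edges are dropped with a warning;
    duplicates keep the maximum weight.  Lines starting with ``#`` are
    comments, except a ``#nodes:`` header that declares isolated nodes.
    """
    nodes: set[str] = set()
    weight: dict[tuple[str, str], float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#nodes:"):
                    nodes.update(tok for tok in line[len("#nodes:"):].split() if tok)
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) not in (2, 3):
                raise NetworkFormatError(f"{path}:{lineno}: expected 'u<TAB>v[<TAB>w]', got {line!r}")
            u, v = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            else:
                w = 1.0
            if not (0.0 <= w <= 1.0):
                raise ValidationError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                nodes.add(u)
                continue
            nodes.update((u, v))
            key = _edge_key(u, v)
            if key in weight:
                logger.warning("%s:%d: duplicate edge (%r, %r); keeping max weight", path, lineno, u, v)
                weight[key] = max(weight[key], w)
            else:
                weight[key] = w
    return Network(id, nodes, weight)


def write_network(net: Network, path) -> None:
    """Write a network as an edge-list TSV (round-trips with read_network)."""
    isolated = sorted(net.nodes - {n for e in net.weight for n in e})
    with open(path, "wt", encoding="utf-8") as fh:
        if isolated:
            fh.write("#nodes: " + " ".join(isolated) + "\n")
        for (u, v) in sorted(net.weight):
            fh.write(f"{u}\t{v}\t{net.weight[(u, v)]!r}\n")


def read_query(path, id: str = "query") -> QueryTree:
    """Read a query tree (same format as read_network, tree invariant checked)."""
    net = read_network(path, id=id)
    return QueryTree(net.id, net.nodes, net.weight)


def read_similarity(path) -> SimilarityMatrix:
    """Read a 3-column TSV ``q_node<TAB>t_node<TAB>sim``; duplicates keep max."""
    sim = SimilarityMatrix()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise NetworkFormatError(f"{path}:{lineno}: expected 'q<TAB>t<TAB>sim', got {line!r}")
            q, t = parts[0], parts[1]
            try:
                s = float(parts[2])
            except ValueError as exc:
                raise NetworkFormatError(f"{path}:{lineno}: bad similarity {parts[2]!r}") from exc
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"{path}:{lineno}: similarity {s} outside [0, 1]")
            prev = sim.get(q, t)
            if (q, t) in dict(sim.items()):
                logger.warning("%s:%d: duplicate pair (%r, %r); keeping max", path, lineno, q, t)
            sim.set(q, t, max(prev, s))
    return sim


def write_similarity(sim: SimilarityMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for (q, t) in sorted(dict(sim.items())):
            fh.write(f"{q}\t{t}\t{sim.get(q, t)!r}\n")


def similarity_from_evalues(
    evalues: Mapping[tuple[str, str], float], floor: float = 1e-180
) -> SimilarityMatrix:
    """Similarity as the normalized negative log10 of BLAST-style E-values.

    ``sim = clip(-log10(max(E, floor)), 0, .) / -log10(floor)`` so that
    E <= floor gives 1.0 and E >= 1 gives 0.0.
    """
    if not (0.0 < floor < 1.0):
        raise ValidationError("E-value floor must be in (0, 1)")
    denom = -math.log10(floor)
    sim = SimilarityMatrix()
    for (q, t), e in evalues.items():
        e = float(e)
        if e <= 0.0:
            raise ValidationError(f"non-positive E-value for pair ({q!r}, {t!r})")
        raw = -math.log10(max(e, floor))
        sim.set(q, t, max(0.0, raw) / denom)
    return sim
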