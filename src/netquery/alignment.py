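"""Confidence-bounded color-coding alignment of a tree query against a target.

The query network is a tree; the target is an arbitrary weighted network.
An alignment maps each query node either to a distinct target node or to
"deleted" (at most ``max_del`` deletions), and may pull in up to ``max_ins``
extra target nodes ("insertions") to bridge query edges whose endpoint images
are not adjacent, so that the alignment subnetwork (images plus insertions)
is connected.  The score of an alignment is

    sum of sim(u, alpha(u)) over matched query nodes
  + sum of w(alpha(u), alpha(v)) over query edges realized as a direct
    target edge (endpoint images adjacent, no bridging insertions)
  + n_ins * delta_ins + n_del * delta_del

with nonpositive indel penalties.  ``colorcode_align`` finds the optimum with
probability at least the requested confidence by repeating a dynamic program
restricted to "colorful" solutions (all used target nodes receive distinct
colors under a random coloring) for a calibrated number of trials.
``brute_force_align`` is an exhaustive oracle for small instances.

Model conventions shared by both engines (the classic formulation leaves
these open; see docs/methods.md):

* the query tree is rooted at a maximum-degree node (lexicographic
  tie-break); deleting a query node splices its children to its parent, and
  the canonical root itself is never deleted;
* a query edge realized across non-adjacent images is bridged by a simple
  target path whose interior nodes are insertions; bridging paths of distinct
  query edges have disjoint interiors;
* with ``count_bridge_weights`` enabled the weights of bridging-path edges
  are added to the score (off by default, keeping the printed formula).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import Network, QueryTree, ScoringParams, SimilarityMatrix, ValidationError

__all__ = [
    "Alignment",
    "InstanceTooLarge",
    "score_alignment",
    "trials_for_confidence",
    "colorcode_align",
    "brute_force_align",
    "canonical_root",
    "write_alignment",
]


class InstanceTooLarge(ValidationError):
    """Raised when the exhaustive oracle is asked for an oversized instance."""


@dataclass(frozen=True)
class Alignment:
    """A query-to-target alignment with indels.

    matched: injective map query node -> target node.
    deleted_query: query nodes aligned to nothing.
    inserted_target: target nodes pulled in to bridge query edges, in
        discovery order.
    bridges: realized bridging paths, keyed by the (contracted) query edge
        (parent, child); each value is the full target path including both
        endpoint images.  Only paths with interior nodes are recorded.
    score: alignment score (consistent with :func:`score_alignment`).
    subnetwork_nodes: images of matched nodes plus insertions; the induced
        target subgraph on these nodes is connected.
    """

    matched: Mapping[str, str]
    deleted_query: frozenset[str]
    inserted_target: tuple[str, ...]
    score: float
    subnetwork_nodes: frozenset[str]
    bridges: Mapping[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_ins(self) -> int:
        return len(self.inserted_target)

    @property
    def n_del(self) -> int:
        return len(self.deleted_query)

    def validate(self, q: QueryTree, t: Network, sim: SimilarityMatrix, p: ScoringParams) -> None:
        """Check all Alignment invariants; raise ValidationError on failure."""
        images = list(self.matched.values())
        if len(set(images)) != len(images):
            raise ValidationError("matched map is not injective")
        if set(self.matched) | set(self.deleted_query) != set(q.nodes) or (
            set(self.matched) & set(self.deleted_query)
        ):
            raise ValidationError("matched and deleted_query must partition the query nodes")
        if self.n_ins > p.max_ins or self.n_del > p.max_del:
            raise ValidationError("indel caps exceeded")
        if set(self.inserted_target) & set(images):
            raise ValidationError("inserted nodes overlap matched images")
        if self.subnetwork_nodes != frozenset(images) | frozenset(self.inserted_target):
            raise ValidationError("subnetwork_nodes inconsistent with matched/inserted")
        if self.subnetwork_nodes:
            import networkx as nx

            sub = t.subnetwork(self.subnetwork_nodes).to_networkx()
            if not nx.is_connected(sub):
                raise ValidationError("alignment subnetwork is not connected")
        recomputed = score_alignment(self, q, t, sim, p)
        if not math.isclose(recomputed, self.score, rel_tol=1e-9, abs_tol=1e-9):
            raise ValidationError(f"stored score {self.score} != recomputed {recomputed}")


def _make_alignment(matched, deleted, inserted, bridges, q, t, sim, p) -> Alignment:
    a = Alignment(
        matched=dict(matched),
        deleted_query=frozenset(deleted),
        inserted_target=tuple(inserted),
        score=0.0,
        subnetwork_nodes=frozenset(matched.values()) | frozenset(inserted),
        bridges=dict(bridges),
    )
    score = score_alignment(a, q, t, sim, p)
    return Alignment(a.matched, a.deleted_query, a.inserted_target, score, a.subnetwork_nodes, a.bridges)


def score_alignment(
    a: Alignment, q: QueryTree, t: Network, sim: SimilarityMatrix, p: ScoringParams
) -> float:
    """Score an alignment by the standard formula (see module docstring)."""
    images = list(a.matched.values())
    if len(set(images)) != len(images):
        raise ValidationError("matched map is not injective")
    total = 0.0
    for u, v in sorted(a.matched.items()):
        total += sim.get(u, v)
    bridged = {frozenset(edge) for edge in a.bridges}
    for (u, v) in sorted(q.edges):
        if frozenset((u, v)) in bridged:
            continue  # realized across insertions, not as a direct edge
        if u in a.matched and v in a.matched and t.has_edge(a.matched[u], a.matched[v]):
            total += t.edge_weight(a.matched[u], a.matched[v])
    if p.count_bridge_weights:
        for edge in sorted(a.bridges):
            path = a.bridges[edge]
            for x, y in zip(path, path[1:]):
                total += t.edge_weight(x, y)
    total += a.n_ins * p.delta_ins + a.n_del * p.delta_del
    return total


def trials_for_confidence(num_colors: int, confidence: float) -> int:
    """Number of random-coloring trials so a fixed optimal node set of at most
    ``num_colors`` nodes is colorful in at least one trial with probability
    >= confidence.  Uses the conservative colorful probability c!/c^c."""
    if not (0.0 < confidence < 1.0):
        raise ValidationError("confidence must be in (0, 1)")
    c = int(num_colors)
    if c < 1:
        raise ValidationError("need at least one color")
    p_colorful = math.factorial(c) / c**c
    if p_colorful >= 1.0:
        return 1
    return math.ceil(math.log(1.0 - confidence) / math.log(1.0 - p_colorful))


# ---------------------------------------------------------------------------
# Shared rooted-tree plumbing


def canonical_root(q: QueryTree) -> str:
    """Root at a maximum-degree node, lexicographically smallest on ties."""
    deg = {u: len(q.neighbors(u)) for u in q.nodes}
    maxdeg = max(deg.values())
    return min(u for u, d in deg.items() if d == maxdeg)


def _rooted_children(q: QueryTree, root: str) -> dict[str, list[str]]:
    children: dict[str, list[str]] = {u: [] for u in q.nodes}
    seen = {root}
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(q.neighbors(u)):
            if v not in seen:
                seen.add(v)
                children[u].append(v)
                stack.append(v)
    return children


def _contract(root: str, children: Mapping[str, list[str]], deleted: set[str]):
    """Contracted rooted tree after splicing deleted nodes' children upward.

    Returns ``{kept node: [(kept child, is_original_edge), ...]}``.  A child
    reached through one or more deleted nodes carries ``is_original_edge``
    False (its spliced edge is not in the query edge set)."""

    def kept_below(u: str) -> list[str]:
        out: list[str] = []
        for ch in children[u]:
            if ch in deleted:
                out.extend(kept_below(ch))
            else:
                out.append(ch)
        return out

    result: dict[str, list[tuple[str, bool]]] = {}
    stack = [root]
    while stack:
        u = stack.pop()
        lst: list[tuple[str, bool]] = []
        for ch in children[u]:
            if ch in deleted:
                lst.extend((g, False) for g in kept_below(ch))
            else:
                lst.append((ch, True))
        result[u] = lst
        stack.extend(node for node, _ in lst)
    return result


def _check_forced(q: QueryTree, t: Network, forced) -> dict[str, str]:
    forced = dict(forced or {})
    for u, v in forced.items():
        if u not in q.nodes:
            raise ValidationError(f"forced query node {u!r} not in query")
        if v not in t.nodes:
            raise ValidationError(f"forced target node {v!r} not in target")
    if len(set(forced.values())) != len(forced):
        raise ValidationError("forced map is not injective")
    return forced


# ---------------------------------------------------------------------------
# Exhaustive oracle


def brute_force_align(
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    p: ScoringParams,
    forced: Mapping[str, str] | None = None,
) -> Alignment | None:
    """Exact optimum by exhaustive enumeration (testing oracle; tiny instances).

    Enumerates every deletion subset, every injective assignment of the
    contracted tree consistent with ``forced``, and every disjoint-interior
    bridging-path realization within the insertion budget.
    """
    if q.n_nodes > 6 or t.n_nodes > 14:
        raise InstanceTooLarge(
            f"brute force limited to <=6 query and <=14 target nodes, got {q.n_nodes}/{t.n_nodes}"
        )
    forced = _check_forced(q, t, forced)
    forced_targets = set(forced.values())
    root = canonical_root(q)
    children = _rooted_children(q, root)
    tnodes = sorted(t.nodes)

    # simple bridging paths between ordered target pairs, by interior tuple
    paths: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    for a in tnodes:
        for b in tnodes:
            if a == b:
                continue
            opts: list[tuple[str, ...]] = []
            if t.has_edge(a, b):
                opts.append(())
            if p.max_ins >= 1:
                for m in sorted(t.neighbors(a) & t.neighbors(b)):
                    opts.append((m,))
            if p.max_ins >= 2:
                for m1 in sorted(t.neighbors(a) - {b}):
                    for m2 in sorted(t.neighbors(b) & t.neighbors(m1) - {a, m1}):
                        opts.append((m1, m2))
            paths[(a, b)] = opts

    best: Alignment | None = None
    best_key: tuple[float, int] | None = None  # (score, -total indels)

    deletable = sorted(set(q.nodes) - {root} - set(forced))
    for ndel in range(0, min(p.max_del, len(deletable)) + 1):
        for dset in itertools.combinations(deletable, ndel):
            deleted = set(dset)
            ctree = _contract(root, children, deleted)
            # breadth-first order guarantees a parent is assigned before its edges
            order: list[tuple[str, str, bool]] = []
            queue = [root]
            while queue:
                u = queue.pop(0)
                for ch, flag in ctree[u]:
                    order.append((u, ch, flag))
                    queue.append(ch)
            del_penalty = ndel * p.delta_del

            def consider(amap, interiors, bridges, partial):
                nonlocal best, best_key
                score = partial + del_penalty
                n_indel = len(interiors) + ndel
                key = (score, -n_indel)
                if best_key is not None:
                    if key < best_key:
                        return
                    if key == best_key and tuple(sorted(amap.items())) >= tuple(
                        sorted(best.matched.items())
                    ):
                        return
                cand = _make_alignment(amap, deleted, interiors, bridges, q, t, sim, p)
                best, best_key = cand, (cand.score, -n_indel)

            def recurse(i: int, amap, used: set, interiors: list, bridges: dict, partial: float):
                if i == len(order):
                    consider(amap, interiors, bridges, partial)
                    return
                pu, ch, flag = order[i]
                pv = amap[pu]
                if ch in forced:
                    candidates = [forced[ch]] if forced[ch] not in used else []
                else:
                    candidates = [v for v in tnodes if v not in used and v not in forced_targets]
                ins_left = p.max_ins - len(interiors)
                for v2 in candidates:
                    base_gain = sim.get(ch, v2)
                    for interior in paths[(pv, v2)]:
                        if len(interior) > ins_left:
                            continue
                        if any(m in used or m == v2 or m in forced_targets for m in interior):
                            continue
                        gain = base_gain + len(interior) * p.delta_ins
                        if not interior and flag and t.has_edge(pv, v2):
                            gain += t.edge_weight(pv, v2)
                        if interior and p.count_bridge_weights:
                            full = (pv, *interior, v2)
                            gain += sum(t.edge_weight(x, y) for x, y in zip(full, full[1:]))
                        amap[ch] = v2
                        added = set(interior) | {v2}
                        used.update(added)
                        if interior:
                            bridges[(pu, ch)] = (pv, *interior, v2)
                        interiors.extend(interior)
                        recurse(i + 1, amap, used, interiors, bridges, partial + gain)
                        for _ in interior:
                            interiors.pop()
                        bridges.pop((pu, ch), None)
                        used.difference_update(added)
                        del amap[ch]

            root_candidates = (
                [forced[root]] if root in forced else [v for v in tnodes if v not in forced_targets]
            )
            for rv in root_candidates:
                recurse(0, {root: rv}, {rv}, [], {}, sim.get(root, rv))
    return best


# ---------------------------------------------------------------------------
# Color-coding dynamic program (vectorized across trials)


@functools.lru_cache(maxsize=None)
def _disjoint_pairs(c: int):
    """All (A, B) subset pairs with A & B == 0, grouped by union for reduceat.

    Returns (p1, p2, starts): index arrays of length 3^c sorted by A|B, and
    the start offset of each union value 0..2^c-1."""
    S = 1 << c
    groups: list[list[tuple[int, int]]] = [[] for _ in range(S)]
    for union in range(S):
        sub = union
        while True:
            groups[union].append((sub, union ^ sub))
            if sub == 0:
                break
            sub = (sub - 1) & union
    p1, p2, starts = [], [], []
    pos = 0
    for union in range(S):
        starts.append(pos)
        for a, b in groups[union]:
            p1.append(a)
            p2.append(b)
        pos += len(groups[union])
    return np.asarray(p1), np.asarray(p2), np.asarray(starts)


class _ColorDP:
    """One chunk of color-coding trials, vectorized over the trial axis."""

    def __init__(self, q, t, sim, p, forced, colors, count_bridge_weights):
        self.q, self.t, self.sim, self.p = q, t, sim, p
        self.forced = forced
        self.cbw = count_bridge_weights
        self.tnodes = sorted(t.nodes)
        self.tindex = {v: i for i, v in enumerate(self.tnodes)}
        n = len(self.tnodes)
        self.n = n
        self.colors = colors  # (T, n) ints
        self.T = colors.shape[0]
        self.A = np.zeros((n, n), dtype=bool)
        self.W = np.zeros((n, n), dtype=np.float64)
        for (u, v), w in t.weight.items():
            i, j = self.tindex[u], self.tindex[v]
            self.A[i, j] = self.A[j, i] = True
            self.W[i, j] = self.W[j, i] = w
        self.adj = [np.nonzero(self.A[i])[0] for i in range(n)]
        self.forced_t_idx = {self.tindex[v] for v in forced.values()}
        self.root = canonical_root(q)
        self.children = _rooted_children(q, self.root)
        self.memo: dict = {}
        self.attach_memo: dict = {}

    def setup(self, c: int):
        self.c = c
        self.S = 1 << c
        self.I = self.p.max_ins + 1
        self.D = self.p.max_del + 1
        self.p1, self.p2, self.starts = _disjoint_pairs(c)
        # submasks without bit k, for insertion color shifts
        self.subsets_wo = []
        for k in range(c):
            wo = np.asarray([s for s in range(self.S) if not s & (1 << k)])
            self.subsets_wo.append(wo)
        self.bit = [1 << k for k in range(c)]

    def _empty(self):
        return np.full((self.T, self.n, self.S, self.I, self.D), -np.inf)

    def simvec(self, u: str) -> np.ndarray:
        return np.asarray([self.sim.get(u, v) for v in self.tnodes])

    def base(self, u: str) -> np.ndarray:
        B = self._empty()
        if u in self.forced:
            fv = self.tindex[self.forced[u]]
            B[:, fv, 0, 0, 0] = self.sim.get(u, self.forced[u])
        else:
            allowed = np.asarray(
                [i for i in range(self.n) if i not in self.forced_t_idx], dtype=int
            )
            if allowed.size:
                sims = self.simvec(u)[allowed]
                subs = 1 << self.colors[:, allowed]  # (T, |allowed|)
                tr = np.arange(self.T)[:, None]
                B[tr, allowed[None, :], subs, 0, 0] = sims[None, :]
        return B

    @staticmethod
    def _active(table: np.ndarray) -> np.ndarray:
        """(I, D) mask of insertion/deletion slices holding any finite value."""
        return np.isfinite(table).any(axis=(0, 1, 2))

    def _add_insertion_slice(self, arr: np.ndarray, m: int) -> np.ndarray:
        """Insert target node m into a (T, S) slice: consume m's per-trial
        color bit and add delta_ins (the caller moves the result one
        insertion slot up)."""
        out = np.full_like(arr, -np.inf)
        for k in range(self.c):
            tr = np.nonzero(self.colors[:, m] == k)[0]
            if tr.size == 0:
                continue
            src = self.subsets_wo[k]
            dst = src | self.bit[k]
            out[tr[:, None], dst[None, :]] = arr[tr[:, None], src[None, :]] + self.p.delta_ins
        return out

    def attach(self, ch: str, orig_edge: bool) -> np.ndarray:
        """Best contribution of child ch's subtree as a function of the
        parent's placement v: direct match at a neighbor of v, or across a
        bridging path of insertions."""
        key = (ch, orig_edge)
        if key in self.attach_memo:
            return self.attach_memo[key]
        Dch = self.table(ch, tuple((g, True) for g in self.children[ch]))
        E = self._empty()
        active = self._active(Dch)
        for i in range(self.I):
            for d in range(self.D):
                if not active[i, d]:
                    continue
                sl = Dch[:, :, :, i, d]  # (T, n, S)
                # direct (path length 1)
                for v in range(self.n):
                    nb = self.adj[v]
                    if nb.size == 0:
                        continue
                    cand = sl[:, nb]
                    if orig_edge:
                        cand = cand + self.W[v, nb][None, :, None]
                    np.maximum(E[:, v, :, i, d], cand.max(axis=1), out=E[:, v, :, i, d])
                if self.p.max_ins < 1 or i + 1 >= self.I:
                    continue
                for m in range(self.n):
                    if m in self.forced_t_idx:
                        continue
                    nb = self.adj[m]
                    if nb.size == 0:
                        continue
                    cand = sl[:, nb]
                    if self.cbw:
                        cand = cand + self.W[m, nb][None, :, None]
                    Dnb = cand.max(axis=1)  # (T, S)
                    Em = self._add_insertion_slice(Dnb, m)
                    for v in nb:
                        contrib = Em + self.W[v, m] if self.cbw else Em
                        np.maximum(E[:, v, :, i + 1, d], contrib, out=E[:, v, :, i + 1, d])
                    if i + 2 >= self.I:
                        continue
                    # two-interior paths v - m2 - m - v' (m is the interior
                    # adjacent to the child side)
                    for m2 in nb:
                        if m2 in self.forced_t_idx:
                            continue
                        step = Em + self.W[m2, m] if self.cbw else Em
                        Em2 = self._add_insertion_slice(step, m2)
                        for v in self.adj[m2]:
                            contrib = Em2 + self.W[v, m2] if self.cbw else Em2
                            np.maximum(E[:, v, :, i + 2, d], contrib, out=E[:, v, :, i + 2, d])
        self.attach_memo[key] = E
        return E

    def combine(self, P: np.ndarray, E: np.ndarray) -> np.ndarray:
        out = np.full_like(P, -np.inf)
        actP, actE = self._active(P), self._active(E)
        for i1 in range(self.I):
            for i2 in range(self.I - i1):
                for d1 in range(self.D):
                    for d2 in range(self.D - d1):
                        if not (actP[i1, d1] and actE[i2, d2]):
                            continue
                        A = P[:, :, self.p1, i1, d1]
                        B = E[:, :, self.p2, i2, d2]
                        red = np.maximum.reduceat(A + B, self.starts, axis=2)
                        np.maximum(
                            out[:, :, :, i1 + i2, d1 + d2],
                            red,
                            out=out[:, :, :, i1 + i2, d1 + d2],
                        )
        return out

    def table(self, u: str, lst: tuple) -> np.ndarray:
        key = (u, lst)
        if key in self.memo:
            return self.memo[key]
        if not lst:
            res = self.base(u)
        else:
            (c0, flag), rest = lst[0], lst[1:]
            prev = self.table(u, rest)
            res = self.combine(prev, self.attach(c0, flag))
            if c0 not in self.forced and self.p.max_del >= 1:
                spliced = tuple((g, False) for g in self.children[c0])
                alt = self.table(u, spliced + rest)
                shifted = np.full_like(alt, -np.inf)
                shifted[:, :, :, :, 1:] = alt[:, :, :, :, : self.D - 1] + self.p.delta_del
                res = np.maximum(res, shifted)
        self.memo[key] = res
        return res

    def root_table(self) -> np.ndarray:
        return self.table(self.root, tuple((g, True) for g in self.children[self.root]))


def _backtrack(dp: _ColorDP, v: int, C: int, i: int, d: int):
    """Reconstruct one optimal alignment from a single-trial (T=1) DP.

    Values are recomposed with the same floating-point operations the tables
    used, so exact equality identifies the taken decisions."""
    colors = dp.colors[0]
    matched: dict[str, str] = {}
    deleted: set[str] = set()
    inserted: list[str] = []
    bridges: dict[tuple[str, str], tuple[str, ...]] = {}

    def walk(u: str, lst: tuple, v: int, C: int, i: int, d: int, val: float) -> None:
        if not lst:
            matched[u] = dp.tnodes[v]
            return
        (c0, flag), rest = lst[0], lst[1:]
        prev_tab = dp.table(u, rest)[0]
        Dch = dp.table(c0, tuple((g, True) for g in dp.children[c0]))[0]
        # option: match c0 (scan partitions; prefer fewer insertions, lex order)
        sub = C
        partitions = []
        while True:
            partitions.append(sub)
            if sub == 0:
                break
            sub = (sub - 1) & C
        for i2 in range(i + 1):  # insertions consumed on the child side, ascending
            i1 = i - i2
            for d1 in range(d + 1):
                d2 = d - d1
                for C1 in partitions:
                    C2 = C ^ C1
                    prev = prev_tab[v, C1, i1, d1]
                    if prev == -np.inf:
                        continue
                    # path length 1
                    if i2 >= 0:
                        for v2 in dp.adj[v]:
                            cand = Dch[v2, C2, i2, d2]
                            if cand == -np.inf:
                                continue
                            if flag:
                                cand = cand + dp.W[v, v2]
                            if prev + cand == val:
                                walk(u, rest, v, C1, i1, d1, prev)
                                walk(
                                    c0,
                                    tuple((g, True) for g in dp.children[c0]),
                                    v2,
                                    C2,
                                    i2,
                                    d2,
                                    Dch[v2, C2, i2, d2],
                                )
                                return
                    # one interior insertion: v - m - v2
                    if i2 >= 1:
                        for m in dp.adj[v]:
                            if m in dp.forced_t_idx:
                                continue
                            k = colors[m]
                            if not C2 & (1 << k):
                                continue
                            C2m = C2 ^ (1 << k)
                            for v2 in dp.adj[m]:
                                base_v = Dch[v2, C2m, i2 - 1, d2]
                                if base_v == -np.inf:
                                    continue
                                cand = base_v
                                if dp.cbw:
                                    cand = cand + dp.W[m, v2]
                                cand = cand + dp.p.delta_ins
                                if dp.cbw:
                                    cand = cand + dp.W[v, m]
                                if prev + cand == val:
                                    inserted.append(dp.tnodes[m])
                                    bridges[(u, c0)] = (dp.tnodes[v], dp.tnodes[m], dp.tnodes[v2])
                                    walk(u, rest, v, C1, i1, d1, prev)
                                    walk(
                                        c0,
                                        tuple((g, True) for g in dp.children[c0]),
                                        v2,
                                        C2m,
                                        i2 - 1,
                                        d2,
                                        Dch[v2, C2m, i2 - 1, d2],
                                    )
                                    return
                    # two interior insertions: v - m2 - m - v2
                    if i2 >= 2:
                        for m2 in dp.adj[v]:
                            if m2 in dp.forced_t_idx:
                                continue
                            k2 = colors[m2]
                            if not C2 & (1 << k2):
                                continue
                            for m in dp.adj[m2]:
                                if m in dp.forced_t_idx or m == m2:
                                    continue
                                k = colors[m]
                                if k == k2 or not C2 & (1 << k):
                                    continue
                                C2mm = C2 ^ (1 << k2) ^ (1 << k)
                                for v2 in dp.adj[m]:
                                    base_v = Dch[v2, C2mm, i2 - 2, d2]
                                    if base_v == -np.inf:
                                        continue
                                    cand = base_v
                                    if dp.cbw:
                                        cand = cand + dp.W[m, v2]
                                    cand = cand + dp.p.delta_ins
                                    if dp.cbw:
                                        cand = cand + dp.W[m2, m]
                                    cand = cand + dp.p.delta_ins
                                    if dp.cbw:
                                        cand = cand + dp.W[v, m2]
                                    if prev + cand == val:
                                        inserted.extend([dp.tnodes[m2], dp.tnodes[m]])
                                        bridges[(u, c0)] = (
                                            dp.tnodes[v],
                                            dp.tnodes[m2],
                                            dp.tnodes[m],
                                            dp.tnodes[v2],
                                        )
                                        walk(u, rest, v, C1, i1, d1, prev)
                                        walk(
                                            c0,
                                            tuple((g, True) for g in dp.children[c0]),
                                            v2,
                                            C2mm,
                                            i2 - 2,
                                            d2,
                                            Dch[v2, C2mm, i2 - 2, d2],
                                        )
                                        return
        # option: delete c0
        if c0 not in dp.forced and d >= 1:
            spliced = tuple((g, False) for g in dp.children[c0])
            alt = dp.table(u, spliced + rest)[0]
            cand = alt[v, C, i, d - 1] + dp.p.delta_del
            if cand == val:
                deleted.add(c0)
                walk(u, spliced + rest, v, C, i, d - 1, alt[v, C, i, d - 1])
                return
        raise AssertionError("backtrack failed to reproduce a DP decision")

    lst0 = tuple((g, True) for g in dp.children[dp.root])
    val = dp.root_table()[0, v, C, i, d]
    walk(dp.root, lst0, v, C, i, d, val)
    return matched, deleted, inserted, bridges


def colorcode_align(
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    p: ScoringParams,
    forced: Mapping[str, str] | None = None,
    seed: int = 0,
) -> Alignment | None:
    """Color-coding alignment of tree query ``q`` against target ``t``.

    Runs the calibrated number of independent random colorings (colors
    ``c = #unforced query nodes + max_ins``; trial j is seeded with
    ``seed + j``), solves the colorful tree DP exactly per trial, and returns
    the best alignment found, or None when no feasible alignment exists.
    The returned score is optimal among alignments respecting ``forced`` with
    probability at least ``p.confidence``.
    """
    if not isinstance(q, QueryTree):
        q = QueryTree(q.id, q.nodes, q.weight)  # raises if not a tree
    forced = _check_forced(q, t, forced)
    if t.n_nodes == 0:
        return None
    n_unforced = q.n_nodes - len(forced)
    c = n_unforced + p.max_ins
    ntrials = trials_for_confidence(c, p.confidence) if c >= 1 else 1
    c_eff = max(c, 1)
    n = t.n_nodes
    S = 1 << c_eff
    # trial chunking keeps table memory modest
    per_trial = n * S * (p.max_ins + 1) * (p.max_del + 1)
    chunk = max(1, min(ntrials, 1_500_000 // max(per_trial, 1)))

    best_val = -np.inf
    best_trial = -1
    trial0 = 0
    while trial0 < ntrials:
        tchunk = min(chunk, ntrials - trial0)
        colors = np.stack(
            [
                np.random.default_rng(seed + trial0 + j).integers(0, c_eff, size=n)
                for j in range(tchunk)
            ]
        )
        dp = _ColorDP(q, t, sim, p, forced, colors, p.count_bridge_weights)
        dp.setup(c_eff)
        R = dp.root_table()
        per_trial_best = R.reshape(tchunk, -1).max(axis=1)
        j = int(np.argmax(per_trial_best))
        if per_trial_best[j] > best_val:
            best_val = float(per_trial_best[j])
            best_trial = trial0 + j
        trial0 += tchunk
    if not np.isfinite(best_val):
        return None

    # exact re-run of the winning trial for reconstruction
    colors = np.random.default_rng(seed + best_trial).integers(0, c_eff, size=n)[None, :]
    dp = _ColorDP(q, t, sim, p, forced, colors, p.count_bridge_weights)
    dp.setup(c_eff)
    R = dp.root_table()[0]  # (n, S, I, D)
    val = R.max()
    # entry selection: max value, then min indels, then lexicographic target
    cand_entries = np.argwhere(R == val)
    cand_entries = sorted(
        map(tuple, cand_entries), key=lambda e: (e[2] + e[3], dp.tnodes[e[0]], e[1])
    )
    v, C, i, d = cand_entries[0]
    matched, deleted, inserted, bridges = _backtrack(dp, v, C, i, d)
    return _make_alignment(matched, deleted, inserted, bridges, q, t, sim, p)


def write_alignment(a: Alignment | None, path, z: float | None = None) -> None:
    """Serialize an alignment as TSV: (query_node, target_node|'-', role)."""
    with open(path, "wt", encoding="utf-8") as fh:
        if a is None:
            fh.write("#score=nan\n")
            return
        fh.write(f"#score={a.score!r}\n")
        if z is not None:
            fh.write(f"#zscore={z!r}\n")
        for u in sorted(a.matched):
            fh.write(f"{u}\t{a.matched[u]}\tmatch\n")
        for u in sorted(a.deleted_query):
            fh.write(f"{u}\t-\tdel\n")
        for v in a.inserted_target:
            fh.write(f"-\t{v}\tins\n")
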