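"""Statistical significance of alignment scores.

The null distribution is built from random, topology-preserving, indel-free
embeddings of the query tree into the target: a random image is drawn for the
root and each query edge is mapped onto a uniformly random unused neighbor of
its parent's image.  Each embedding is scored with the standard alignment
formula (every query edge maps to a target edge by construction), and the
observed score is summarized as z = (s - mu) / sigma.
"""

from __future__ import annotations

import random as _random
import statistics
from dataclasses import dataclass

from .alignment import Alignment, canonical_root, _rooted_children
from .network import Network, QueryTree, ScoringParams, SimilarityMatrix, ValidationError

__all__ = [
    "NullDistribution",
    "NullModelError",
    "UndefinedZScoreError",
    "sample_null_scores",
    "z_score",
    "is_significant",
    "DEFAULT_N_NULL",
    "DEFAULT_CUTOFF",
]

#: number of random alignments in the null (10,000, the standard setting)
DEFAULT_N_NULL = 10_000
#: default z-score cut-off (the most permissive value in the studied 3..6 range)
DEFAULT_CUTOFF = 3.0


class NullModelError(RuntimeError):
    """No feasible random embedding found within the retry budget."""


class UndefinedZScoreError(ZeroDivisionError):
    """z-score undefined because the null has zero variance."""


@dataclass(frozen=True)
class NullDistribution:
    """Scores of random topology-preserving embeddings, with mean and sd."""

    scores: tuple[float, ...]
    mean: float
    sd: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.scores) < 2:
            raise ValidationError("a null distribution needs at least 2 samples")
        if self.sd < 0:
            raise ValidationError("standard deviation cannot be negative")


def sample_null_scores(
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    p: ScoringParams,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
) -> NullDistribution:
    """Sample ``n_null`` random indel-free embeddings of ``q`` in ``t``.

    Each embedding picks a uniform random root image, then maps each query
    edge to a uniformly random neighbor of the parent image that is not yet
    used; dead ends discard the attempt.  Raises NullModelError if fewer than
    ``n_null`` embeddings are found within 100 * n_null attempts.
    """
    if t.n_nodes < q.n_nodes:
        raise NullModelError("target smaller than query: no embedding exists")
    root = canonical_root(q)
    children = _rooted_children(q, root)
    # query edges in parent-before-child order
    edge_order: list[tuple[str, str]] = []
    stack = [root]
    while stack:
        u = stack.pop()
        for ch in children[u]:
            edge_order.append((u, ch))
            stack.append(ch)
    tnodes = sorted(t.nodes)
    neigh = {v: sorted(t.neighbors(v)) for v in tnodes}
    qnodes = sorted(q.nodes)
    qedges = sorted(q.edges)  # fixed order keeps float sums reproducible
    rng = _random.Random(seed)
    scores: list[float] = []
    attempts = 0
    max_attempts = 100 * n_null
    while len(scores) < n_null:
        attempts += 1
        if attempts > max_attempts:
            raise NullModelError(
                f"only {len(scores)} of {n_null} embeddings found after {max_attempts} attempts"
            )
        emb = {root: rng.choice(tnodes)}
        used = {emb[root]}
        ok = True
        for (u, ch) in edge_order:
            options = [v for v in neigh[emb[u]] if v not in used]
            if not options:
                ok = False
                break
            v = rng.choice(options)
            emb[ch] = v
            used.add(v)
        if not ok:
            continue
        s = sum(sim.get(u, emb[u]) for u in qnodes)
        for (u, v) in qedges:
            s += t.edge_weight(emb[u], emb[v])
        scores.append(s)
    mean = statistics.fmean(scores)
    sd = statistics.stdev(scores) if len(scores) > 1 else 0.0
    return NullDistribution(tuple(scores), mean, sd, seed)


def z_score(s: float, null: NullDistribution) -> float:
    """Standardized score (s - mu) / sigma against the null."""
    if null.sd == 0:
        raise UndefinedZScoreError("null distribution has zero variance")
    return (s - null.mean) / null.sd


def is_significant(
    a: Alignment,
    q: QueryTree,
    t: Network,
    sim: SimilarityMatrix,
    p: ScoringParams,
    cutoff: float = DEFAULT_CUTOFF,
    n_null: int = DEFAULT_N_NULL,
    seed: int = 0,
    null: NullDistribution | None = None,
) -> tuple[bool, float]:
    """Whether the alignment's z-score reaches ``cutoff`` (inclusive).

    A zero-variance null counts as significant iff the score strictly exceeds
    the null mean (z reported as +inf / -inf / 0 accordingly).  A
    pre-computed ``null`` may be supplied to amortize sampling.
    """
    if null is None:
        null = sample_null_scores(q, t, sim, p, n_null=n_null, seed=seed)
    if null.sd == 0:
        if a.score > null.mean:
            return True, float("inf")
        return False, (0.0 if a.score == null.mean else float("-inf"))
    z = z_score(a.score, null)
    return z >= cutoff, z
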