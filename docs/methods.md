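# Methods

This note records the model implemented by `netquery`, the choices made where
the method leaves room, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## Alignment model

A query is an undirected tree `Q`; the target `T` is an arbitrary undirected
network with edge weights in [0, 1]; node similarity `sim(u, v) ∈ [0, 1]` is
a sparse map (absent pairs are 0).  An alignment maps each query node either
to a distinct target node ("matched") or to nothing ("deleted", at most
`max_del`), and may use up to `max_ins` extra target nodes ("inserted") as
interior nodes of *bridging paths* that realize query edges whose endpoint
images are not adjacent.  The alignment subnetwork — matched images plus
insertions — is always connected.  The score is the sum of matched
similarities, plus the weight of every query edge realized as a direct target
edge, plus `n_ins·δ_ins + n_del·δ_del` with `δ ≤ 0`.

Conventions the underlying formulation leaves open, fixed here (identically
in the production engine and in the exhaustive testing oracle, so that the
oracle comparison is meaningful):

* **Rooting and deletion.**  The query tree is rooted at a maximum-degree
  node (lexicographically smallest on ties).  Deleting a node splices its
  children to its parent; the spliced edges are not query edges and
  contribute no weight even when the images happen to be adjacent.  The
  canonical root itself is never deleted.  (Deletion of a branching node is
  inherently root-dependent — its neighbors must re-attach somewhere — so a
  canonical rooting is required for a well-defined search space.)
* **Bridging.**  A (possibly spliced) tree edge whose endpoint images are at
  distance `d > 1` is realized by a simple target path whose `d−1` interior
  nodes are insertions; bridging paths of distinct edges have disjoint
  interiors.  By default a bridged edge contributes only the insertion
  penalties.  With `ScoringParams(count_bridge_weights=True)` the weights of
  the edges along each bridging path are added instead (the bridge then
  *replaces* the direct-edge term for that query edge — never both).  The
  default keeps the score a function of the matched/deleted/inserted sets
  alone.
* **Tie-breaking.**  Among equal-score alignments the engines prefer fewer
  total indels, then lexicographically smaller placements, making outputs
  deterministic for a fixed seed.

## Color-coding engine

`colorcode_align` repeats, for a calibrated number of trials, a random
uniform coloring of the target with `c = (#query nodes − #forced pairs) +
max_ins` colors followed by an exact tree dynamic program over states
(query node, hosting target node, used-color subset, insertions used,
deletions used) restricted to colorful solutions.  Distinct colors imply
distinct nodes, so every returned alignment is valid; the optimum is missed
only if no trial colors its node set distinctly.

* **Trial calibration.**  A fixed set of at most `c` nodes is colorful with
  probability at least `p = c!/c^c`, so `t = ⌈ln(1−confidence)/ln(1−p)⌉`
  trials find the optimum with the requested confidence (0.99 by default;
  `c = 6` gives 297 trials).  `p` is conservative when fewer than `c` nodes
  are used, so the stated confidence is a lower bound.
* **Forced pairs** (the induced alignment): forced query nodes sit at their
  forced targets, which take no color, are excluded as insertion sites, and
  cannot host other query nodes; forced nodes cannot be deleted.  The color
  count shrinks accordingly, which shrinks the trial count — the main reason
  induced alignments are cheap.
* **Implementation.**  Trials are vectorized (numpy) along a chunked trial
  axis; child subtrees are combined by max-plus reduction over disjoint
  color-subset pairs; only insertion/deletion slices that hold any finite
  value are processed.  Trial `j` draws its coloring from a generator seeded
  with `seed + j`, so results are reproducible and independent of trial
  chunking.  After the best trial is identified, that single trial is re-run
  in float64 and backtracked by exact recomposition of the table arithmetic.
* **Determinism caveat:** score maxima are compared as floats; two
  mathematically tied alignments whose scores differ in the last ulp may
  swap under the tie-break.  This affects which optimal witness is reported,
  never the score.

`brute_force_align` is the testing oracle: it enumerates every deletion
subset, every injective assignment of the contracted tree, and every
disjoint-interior bridging realization, under a hard guard of ≤ 6 query and
≤ 14 target nodes.  It shares the contraction and scoring code paths' model
exactly but none of their machinery.

## Statistical significance

The null distribution embeds the query tree into the target at random with
no indels: a uniform root image, then each tree edge onto a uniform unused
neighbor of the parent's image; dead ends discard the attempt (cap:
100 × n_null attempts).  Each embedding is scored with the standard formula
(every query edge lands on a target edge by construction).  The observed
score is reported as `z = (s − μ)/σ` with the sample standard deviation
(ddof = 1) of `n_null` = 10,000 embeddings by default.  A zero-variance null
is significant iff the score strictly exceeds the null mean.  The null is
*topology-preserving but not degree-preserving*; hub-heavy targets make it
conservative for hub-avoiding queries and vice versa.

## Index construction

Step I grows references by random walks on the target (uniform seed node,
then uniform incident edge to an outside node, until `k` nodes; `k = 6` by
default, matching typical query sizes — the trial count grows steeply with
`k + max_ins`, which bounds practical reference sizes).  Each reference is
aligned repeatedly against a working copy of the target; a mapping is stored
if its z-score (against a null sampled once, on the *original* target)
reaches the cut-off (default 3.0, the permissive end of the useful 3–6
range — it stores the most mappings), and its subnetwork nodes are then
removed from the working copy, so stored mappings are pairwise node-disjoint.
References are added until the union of stored subnetworks covers η % of the
target (default 70; a hard cap of 500 references guards unreachable η).
Step II selects the final reference set by greedy set cover (largest coverage
gain first, creation order on ties), which carries the classic ln-factor
approximation guarantee.  Aligning a reference (a target subtree) back to the
target requires a target×target similarity; the synthetic generator supplies
an identity-based one, and real use supplies a BLAST-derived table.

Index JSON stores the build parameters, an order-independent checksum of the
target's node and weighted edge sets (loading against a different target
fails loudly), each reference's tree, and its ordered mappings.  Rebuilds
with the same seed are byte-identical; all set iterations that feed float
accumulation or RNG draws are explicitly ordered.

## Query processing

For each reference, the query is aligned against it (both small, so cheap)
and the reference is dropped if the score falls below `θ ×` an *ideal score*
(every query node at its best similarity in the reference, every query edge
at the reference's heaviest edge; `θ = 0.5` by default) or if the alignment
has zero total similarity — topology alone, however well it matches, is not
evidence that the reference represents the query.  Surviving references are
processed in descending alignment score.  Composing the query→reference
alignment ψ with a stored reference→target mapping φ forces query node `u`
onto `φ(ψ(u))` whenever both maps are defined **and the pair has positive
similarity** — the composition is only trusted where sequence evidence
supports it, which matters because realistic similarities are sparse (most
protein pairs have no BLAST hit); a composed pair with `sim = 0` is left
free.  For each candidate, the upper bound is the maximum-weight bipartite
matching (scipy's Hungarian solver) of free query nodes against targets
outside the forced image set, plus the forced similarities, plus a
topology-free edge allowance of `|E_Q| ×` the maximum target edge weight
(times `1 + max_ins` when bridging-path weights are counted).  The matching
alone is *not* an upper bound — aligned edges contribute positive weight to
the score — hence the allowance; indel penalties are nonpositive and dropped.
Candidates whose bound cannot beat the incumbent are skipped (a sound bound
makes pruning lossless, which the tests assert directly); the rest run the
induced alignment, and the best result is reported with its z-score and
pruning counters.

## Synthetic data

The generator reproduces the experimental constructions the method is
studied under, with no downloads:

* **Targets:** connected Erdős–Rényi or preferential-attachment graphs with
  a chosen mean degree (2.4 in most fixtures; 4.7 — the densest real
  interactome commonly cited — is a preset), edge weights uniform in
  [0.5, 1].
* **Queries:** random-walk subtrees of the target (6 nodes by default).
* **Topology perturbation:** leaf insertion, edge splitting, deletion of a
  degree-1/2 node — a 6-node query yields 7- and 5-node variants; all
  operations provably return trees.
* **Homology perturbation:** per-residue point mutation of node sequences at
  μ % (uniform over the other 19 amino acids), or a sequence-free surrogate
  that decays each similarity entry toward a uniform [0, 0.1] background by
  the μ fraction.  Sequence-based similarity is the position-wise identity
  fraction — a deliberate stand-in for BLAST-derived tables, which enter via
  `similarity_from_evalues` (normalized −log10 E-value, floor 10⁻¹⁸⁰).
* **Planted motifs:** a query embedded at a random walk site (missing edges
  added), similarity 1.0 on planted pairs; a 25 % random subset of the other
  pairs gets spurious background similarity in (0, 0.1] and the rest none,
  mirroring sparse sequence-search hits.

What passing these experiments shows: the engine is exact up to its stated
confidence, the bound and pruning are sound, the index invariants hold, and
a strongly supported motif is recovered through the index.  What they do not
show: behavior on real interactomes (degree-correlated noise, similarity
biases between paralogs, weight miscalibration), wall-clock competitiveness
with other tools, or recovery when the signal-to-background ratio is far
below the planted regime.

## Problem sizes and parameters in the shipped experiments

The oracle comparisons run on 3–5-node queries against 8–12-node targets
with `max_ins = max_del = 1` (100 seeded instances free, 100 constrained,
1,000 bound candidates); index fixtures use 24-node targets with 4-node
references at η = 60; planted recovery uses 14-node targets, 4-node queries,
full-coverage indexes, cut-off 2.5, `θ = 0.3`, and 50 seeded runs.  These
sizes keep the exhaustive oracle exact and the full suite fast; they are the
package's scaling choice, not a limit of the implementation.  The
planted-recovery experiment uses the permissive `θ = 0.3` because with
sparse similarities the ideal score's edge term dominates, and `θ = 0.5`
screening would discard references that carry the planted signal; `θ`
remains 0.5 by default and is a CLI flag.  Recovery plateaus near ~90–95 %
rather than 100 %: references keep only their walk edges, so the
query-to-reference alignment can be topologically blocked from the
site-consistent placement — the known failure mode of routing queries
through references.

## Defaults

| parameter | default | meaning |
|---|---|---|
| `k`, `m` | 6 | reference / query size (nodes) |
| `eta` | 70 % | index coverage goal (useful range 60–80) |
| `cutoff` | 3.0 | z-score threshold for storing a mapping (range 3–6) |
| `confidence` | 0.99 | color-coding optimality confidence |
| `max_ins`, `max_del` | 2 | indel budget per alignment |
| `delta_ins`, `delta_del` | −0.5 | indel penalties (any nonpositive value) |
| `n_null` | 10,000 | random embeddings per null distribution |
| `theta` | 0.5 | reference-screening fraction of the ideal score |
| E-value floor | 10⁻¹⁸⁰ | E-value treated as maximal similarity |

The indel penalties are a package choice (the formulation requires only
nonpositivity); every default is a config/CLI knob, echoed into every output.
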