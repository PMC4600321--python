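import math

import pytest

from netquery import Network, QueryTree, ScoringParams, SimilarityMatrix
from netquery.alignment import Alignment, brute_force_align, score_alignment
from netquery.index import Mapping, ReferenceNetwork, StaleIndexError, build_index
from netquery.query import (
    IndirectMapping,
    align_to_reference,
    compose_indirect,
    ideal_score,
    induced_align,
    query_index,
    upper_bound,
)
from netquery.synthetic import (
    generate_target,
    identity_similarity,
    plant_motif,
    random_instance,
    sample_query,
)


def psi_alignment(matched, deleted=(), score=1.0):
    return Alignment(
        matched=dict(matched),
        deleted_query=frozenset(deleted),
        inserted_target=(),
        score=score,
        subnetwork_nodes=frozenset(matched.values()),
    )


def make_im(forced, q, ref_id="r", mapping_index=0):
    return IndirectMapping(
        forced=dict(forced),
        free_query=frozenset(q.nodes) - set(forced),
        ref_id=ref_id,
        mapping_index=mapping_index,
    )


@pytest.fixture
def ref_path(path_target):
    tree = QueryTree("r", ["x", "y", "z"], [("x", "y", 1.0), ("y", "z", 1.0)])
    return ReferenceNetwork("r", tree, 0)


class TestScreening:
    def test_zero_similarity_rejected(self, path_query, ref_path, params):
        assert align_to_reference(path_query, ref_path, SimilarityMatrix(), params) is None

    def test_isomorphic_identity_accepted_at_full_theta(self, path_query, ref_path, params):
        sim = SimilarityMatrix({("a", "x"): 1.0, ("b", "y"): 1.0, ("c", "z"): 1.0})
        psi = align_to_reference(path_query, ref_path, sim, params, theta=1.0)
        assert psi is not None and psi.matched == {"a": "x", "b": "y", "c": "z"}
        assert math.isclose(psi.score, ideal_score(path_query, ref_path, sim))

    def test_theta_sweep_has_single_accept_reject_crossing(self, params):
        q, t, sim = random_instance(3, n_target=(6, 6), n_query=(3, 3))
        ref = ReferenceNetwork("r", sample_ref_tree(t), 0)
        decisions = []
        for theta in [i / 20 for i in range(21)]:
            psi = align_to_reference(q, ref, sim, params, theta=theta, seed=1)
            decisions.append(psi is not None)
        # monotone: once rejected, stays rejected
        assert decisions == sorted(decisions, reverse=True)


def sample_ref_tree(t):
    from netquery.index import sample_reference

    return sample_reference(t, k=min(4, t.n_nodes), seed=0).tree


class TestComposeIndirect:
    def test_chain_through_reference(self, path_query):
        psi = psi_alignment({"b": "f"})
        phi = Mapping({"f": "g"}, (), 1.0, 5.0)
        im = compose_indirect(psi, phi, path_query, "r", 0)
        assert im.forced == {"b": "g"}
        assert im.free_query == {"a", "c"}

    def test_deleted_query_node_stays_free(self, path_query):
        psi = psi_alignment({"a": "e"}, deleted=["b"])
        phi = Mapping({"e": "v", "f": "w"}, (), 1.0, 5.0)
        im = compose_indirect(psi, phi, path_query, "r", 0)
        assert im.forced == {"a": "v"} and "b" in im.free_query

    def test_deleted_reference_node_breaks_chain(self, path_query):
        psi = psi_alignment({"a": "e", "b": "f"})
        phi = Mapping({"e": "v", "f": None}, (), 1.0, 5.0)
        im = compose_indirect(psi, phi, path_query, "r", 0)
        assert im.forced == {"a": "v"} and "b" in im.free_query

    def test_identity_composition(self, path_query):
        psi = psi_alignment({"a": "a", "b": "b", "c": "c"})
        phi = Mapping({"a": "a", "b": "b", "c": "c"}, (), 1.0, 5.0)
        im = compose_indirect(psi, phi, path_query, "r", 0)
        assert im.forced == {"a": "a", "b": "b", "c": "c"}
        assert not im.free_query


class TestUpperBound:
    def test_fully_forced_is_similarity_sum_plus_edge_allowance(self, path_query, path_target):
        sim = SimilarityMatrix({("a", "x"): 0.9, ("b", "y"): 0.7, ("c", "z"): 0.8})
        im = make_im({"a": "x", "b": "y", "c": "z"}, path_query)
        ub = upper_bound(path_query, path_target, sim, im)
        # forced similarities plus one max-weight edge per query edge
        assert math.isclose(ub, 0.9 + 0.7 + 0.8 + 2 * 1.0)

    def test_single_free_node_gets_its_best_target_outside_s_prime(
        self, path_query, path_target
    ):
        sim = SimilarityMatrix(
            {("a", "x"): 0.9, ("b", "y"): 0.7, ("c", "z"): 0.6, ("c", "w"): 0.55, ("c", "x"): 0.99}
        )
        im = make_im({"a": "x", "b": "y"}, path_query)
        ub = upper_bound(path_query, path_target, sim, im)
        # c may not take x (in S'); best outside S' is z at 0.6
        assert math.isclose(ub, 0.9 + 0.7 + 0.6 + 2 * 1.0)

    def test_matching_bound_equals_exhaustive_assignment(self, path_target):
        import itertools

        q = QueryTree("q", ["a", "b", "c"], [("a", "b", 1.0), ("b", "c", 1.0)])
        sim = SimilarityMatrix(
            {(u, v): 0.1 * i + 0.2 * j
             for i, u in enumerate(["a", "b", "c"])
             for j, v in enumerate(sorted(path_target.nodes))}
        )
        im = make_im({}, q)
        ub = upper_bound(q, path_target, sim, im)
        best = max(
            sum(sim.get(u, v) for u, v in zip(["a", "b", "c"], combo))
            for combo in itertools.permutations(sorted(path_target.nodes), 3)
        )
        assert math.isclose(ub, best + 2 * 1.0)

    def test_dominates_constrained_optimum(self, params):
        import random

        for seed in range(25):
            q, t, sim = random_instance(seed + 900, n_target=(8, 10), n_query=(3, 4))
            rng = random.Random(seed)
            k = rng.randint(1, 2)
            forced = dict(zip(rng.sample(sorted(q.nodes), k), rng.sample(sorted(t.nodes), k)))
            im = make_im(forced, q)
            ub = upper_bound(q, t, sim, im, params)
            bf = brute_force_align(q, t, sim, params, forced=forced)
            if bf is not None:
                assert ub >= bf.score - 1e-12


class TestInducedAlign:
    def test_fully_forced_feasible_scores_forced_map(self, path_query, path_target, params):
        sim = SimilarityMatrix({("a", "x"): 0.9, ("b", "y"): 0.7, ("c", "z"): 0.8})
        im = make_im({"a": "x", "b": "y", "c": "z"}, path_query)
        a = induced_align(path_query, path_target, sim, im, params, seed=0)
        assert a.matched == im.forced
        ref = Alignment(im.forced, frozenset(), (), 0.0, frozenset(im.forced.values()))
        assert math.isclose(a.score, score_alignment(ref, path_query, path_target, sim, params))

    def test_forced_images_at_distance_two_use_one_insertion(self, path_target, params):
        q = QueryTree("q", ["a", "b"], [("a", "b", 1.0)])
        sim = SimilarityMatrix({("a", "x"): 1.0, ("b", "z"): 1.0})
        im = make_im({"a": "x", "b": "z"}, q)
        a = induced_align(q, path_target, sim, im, params, seed=0)
        assert a is not None and a.n_ins == 1 and a.inserted_target == ("y",)
        assert math.isclose(a.score, 1.0 + 1.0 + params.delta_ins)

    def test_forced_images_too_far_apart_infeasible(self, params):
        nodes = [f"t{i}" for i in range(5)]
        t = Network("t", nodes, [(nodes[i], nodes[i + 1], 1.0) for i in range(4)])
        q = QueryTree("q", ["a", "b"], [("a", "b", 1.0)])
        im = make_im({"a": "t0", "b": "t4"}, q)  # distance 4, 3 interiors needed
        p = ScoringParams(max_ins=2, max_del=2)
        assert induced_align(q, t, SimilarityMatrix(), im, p, seed=0) is None

    def test_matches_constrained_oracle(self, params):
        import random

        hits = feasible = 0
        for seed in range(12):
            q, t, sim = random_instance(seed + 300, n_query=(3, 4))
            rng = random.Random(seed)
            k = rng.randint(1, 2)
            forced = dict(zip(rng.sample(sorted(q.nodes), k), rng.sample(sorted(t.nodes), k)))
            im = make_im(forced, q)
            bf = brute_force_align(q, t, sim, params, forced=forced)
            a = induced_align(q, t, sim, im, params, seed=seed)
            assert (bf is None) == (a is None)
            if bf is not None:
                feasible += 1
                assert a.score <= bf.score + 1e-9
                hits += math.isclose(a.score, bf.score, rel_tol=1e-9)
        assert hits >= feasible - 1


@pytest.fixture(scope="module")
def planted_setup():
    """Target with a planted query motif and an index covering it."""
    p = ScoringParams(max_ins=1, max_del=1)
    tgt = generate_target(14, model="er", density=2.6, seed=21)
    q0 = sample_query(tgt, m=4, seed=33)
    ren = {n: f"q{i}" for i, n in enumerate(sorted(q0.nodes))}
    q = QueryTree("probe", ren.values(), [(ren[a], ren[b], w) for (a, b), w in q0.weight.items()])
    t2, sim_qt, site = plant_motif(tgt, q, seed=8)
    sim_tt = identity_similarity(t2)
    ix = build_index(t2, sim_tt, p, k=4, eta=100, cutoff=2.5, seed=17, n_null=200,
                     max_references=40)
    assert set(site.values()) <= ix.cover_nodes  # the index covers the planted region
    return p, q, t2, sim_qt, site, ix


class TestQueryIndex:
    def test_empty_index_returns_nothing(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        from netquery.index import ReferenceIndex

        empty = ReferenceIndex(ix.target_checksum, ix.params, 0, [], frozenset())
        res = query_index(q, t2, empty, sim_qt, p, seed=0, compute_z=False)
        assert res.best is None and res.total_candidates == 0

    def test_counters_account_for_every_candidate(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        res = query_index(q, t2, ix, sim_qt, p, seed=1, compute_z=False)
        total = sum(len(ms.mappings) for _, ms in ix.references)
        assert res.total_candidates == total
        assert len(res.candidates) == total

    def test_planted_query_recovers_global_optimum(self, planted_setup):
        p, q, t2, sim_qt, site, ix = planted_setup
        res = query_index(q, t2, ix, sim_qt, p, seed=2, n_null=500)
        bf = brute_force_align(q, t2, sim_qt, p)
        assert res.best is not None
        assert math.isclose(res.best.score, bf.score, rel_tol=1e-9)
        assert res.best.matched == site
        assert res.z is not None and res.z > 3.0

    def test_upper_bound_dominates_examined_candidates(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        res = query_index(q, t2, ix, sim_qt, p, seed=3, compute_z=False)
        for rec in res.candidates:
            if rec.outcome == "examined" and rec.induced_score is not None:
                assert rec.upper_bound >= rec.induced_score - 1e-12

    def test_pruning_never_changes_the_best_score(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        pruned = query_index(q, t2, ix, sim_qt, p, seed=4, compute_z=False)
        full = query_index(q, t2, ix, sim_qt, p, seed=4, prune=False, compute_z=False)
        assert full.pruned_by_bound == 0
        assert (pruned.best is None) == (full.best is None)
        if pruned.best is not None:
            assert math.isclose(pruned.best.score, full.best.score, rel_tol=1e-9)

    def test_stale_index_rejected(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        other = generate_target(14, model="er", density=2.6, seed=99)
        with pytest.raises(StaleIndexError):
            query_index(q, other, ix, sim_qt, p, seed=0)

    def test_deterministic_under_fixed_seed(self, planted_setup):
        p, q, t2, sim_qt, _, ix = planted_setup
        r1 = query_index(q, t2, ix, sim_qt, p, seed=5)
        r2 = query_index(q, t2, ix, sim_qt, p, seed=5)
        assert (r1.best is None) == (r2.best is None)
        if r1.best:
            assert r1.best.matched == r2.best.matched and r1.z == r2.z
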