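import itertools
import json
import math

import pytest

from netquery import Network, QueryTree, ScoringParams, SimilarityMatrix
from netquery.index import (
    DEFAULT_K,
    Mapping,
    MappingSet,
    ReferenceNetwork,
    StaleIndexError,
    build_index,
    build_initial_set,
    extract_mappings,
    load_index,
    network_checksum,
    sample_reference,
    save_index,
    select_final_set,
)
from netquery.network import ValidationError
from netquery.synthetic import generate_target, identity_similarity, plant_copies


def path_network(n, prefix="t"):
    nodes = [f"{prefix}{i}" for i in range(n)]
    return Network("path", nodes, [(nodes[i], nodes[i + 1], 1.0) for i in range(n - 1)])


class TestSampleReference:
    def test_single_node_reference(self):
        t = path_network(5)
        r = sample_reference(t, k=1, seed=0)
        assert r.tree.n_nodes == 1 and r.tree.n_edges == 0

    def test_default_reference_size_is_six(self):
        assert DEFAULT_K == 6

    @pytest.mark.parametrize("seed", range(5))
    def test_walk_on_path_yields_contiguous_subpath(self, seed):
        t = path_network(10)
        r = sample_reference(t, k=4, seed=seed)
        idx = sorted(int(n[1:]) for n in r.tree.nodes)
        assert idx == list(range(idx[0], idx[0] + 4))  # an interval
        r.validate_against(t)

    def test_reference_is_subtree_of_target(self):
        t = generate_target(30, model="pa", density=2.4, seed=1)
        r = sample_reference(t, k=6, seed=3)
        assert r.tree.n_nodes == 6 and r.tree.n_edges == 5
        r.validate_against(t)

    def test_too_small_target_rejected(self):
        from netquery.index import BuildError

        with pytest.raises(BuildError):
            sample_reference(path_network(3), k=4, seed=0)


def reference_from_site(t2, motif, sim, site):
    """The planted image of the motif, as a reference subtree of the target."""
    nodes = set(site.values())
    edges = [(site[a], site[b], t2.edge_weight(site[a], site[b])) for (a, b) in motif.edges]
    tree = QueryTree("ref", nodes, edges)
    return ReferenceNetwork("ref", tree, 0), sim.relabel_query(site)


class TestExtractMappings:
    def test_two_planted_copies_recovered(self, params):
        motif = QueryTree("m", ["m0", "m1", "m2", "m3"],
                          [("m0", "m1", 1.0), ("m1", "m2", 1.0), ("m1", "m3", 1.0)])
        tgt = generate_target(40, model="er", density=2.5, seed=12)
        t2, sim, sites = plant_copies(tgt, motif, n_copies=2, seed=3)
        ref, sim_rt = reference_from_site(t2, motif, sim, sites[0])
        mset = extract_mappings(ref, t2, sim_rt, params, cutoff=3.0, seed=5, n_null=500)
        assert len(mset.mappings) >= 2
        mset.validate(cutoff=3.0)
        site_sets = [frozenset(s.values()) for s in sites]
        recovered = [m.subnetwork_nodes for m in mset.mappings[:2]]
        for site in site_sets:
            assert any(site == rec for rec in recovered)

    def test_no_similarity_gives_empty_set(self, params):
        t = generate_target(20, model="pa", density=2.0, seed=2)
        ref = sample_reference(t, k=4, seed=1)
        mset = extract_mappings(ref, t, SimilarityMatrix(), params, cutoff=3.0,
                                seed=2, n_null=300)
        assert mset.mappings == ()

    def test_unequal_mapping_counts_supported(self):
        ms = MappingSet(
            "r",
            (
                Mapping({"a": "x"}, (), 1.0, 5.0),
                Mapping({"a": "y"}, (), 0.9, 4.0),
                Mapping({"a": "z"}, (), 0.8, 3.5),
            ),
        )
        ms.validate(cutoff=3.0)
        assert len(ms.mappings) == 3

    def test_overlapping_mappings_rejected(self):
        ms = MappingSet("r", (Mapping({"a": "x"}, (), 1, 5), Mapping({"a": "x"}, (), 1, 5)))
        with pytest.raises(ValidationError):
            ms.validate(cutoff=3.0)

    def test_cutoff_six_mappings_are_prefix_of_cutoff_three(self, params):
        motif = QueryTree("m", ["m0", "m1", "m2"], [("m0", "m1", 1.0), ("m1", "m2", 1.0)])
        tgt = generate_target(24, model="er", density=2.2, seed=9)
        t2, sim, sites = plant_copies(tgt, motif, n_copies=2, seed=11)
        ref, sim_rt = reference_from_site(t2, motif, sim, sites[0])
        low = extract_mappings(ref, t2, sim_rt, params, cutoff=3.0, seed=4, n_null=400)
        high = extract_mappings(ref, t2, sim_rt, params, cutoff=6.0, seed=4, n_null=400)
        assert len(high.mappings) <= len(low.mappings)
        assert high.mappings == low.mappings[: len(high.mappings)]


def fake_ref(ref_id, cover_targets):
    tree = QueryTree(ref_id, ["n"])
    phi = {"n": cover_targets[0]}
    mappings = [Mapping({"n": v}, (), 1.0, 9.0) for v in cover_targets]
    return (ReferenceNetwork(ref_id, tree, 0), MappingSet(ref_id, tuple(mappings)))


class TestSelectFinalSet:
    def test_single_reference_covering_everything(self):
        initial = [fake_ref("r0", ["1", "2", "3"]), fake_ref("r1", ["2"])]
        final = select_final_set(initial, eta=100.0, n_target_nodes=3)
        assert [r.ref_id for r, _ in final] == ["r0"]

    def test_greedy_on_textbook_cover(self):
        initial = [
            fake_ref("r0", ["1", "2", "3"]),
            fake_ref("r1", ["3", "4"]),
            fake_ref("r2", ["1", "2"]),
        ]
        final = select_final_set(initial, eta=100.0, n_target_nodes=4)
        assert [r.ref_id for r, _ in final] == ["r0", "r1"]

    def test_insufficient_coverage_keeps_all(self):
        initial = [fake_ref("r0", ["1"])]
        final = select_final_set(initial, eta=100.0, n_target_nodes=5)
        assert len(final) == 1

    def test_greedy_within_ln_factor_of_optimum(self):
        # brute-force the optimal cover over all subsets and check the
        # classic ln-approximation guarantee
        import random

        rng = random.Random(0)
        universe = [str(i) for i in range(12)]
        initial = [
            fake_ref(f"r{i}", rng.sample(universe, rng.randint(2, 5))) for i in range(8)
        ]
        total = set()
        for _, ms in initial:
            total |= ms.cover
        eta = 100.0 * len(total) / len(universe)
        final = select_final_set(initial, eta=eta, n_target_nodes=len(universe))
        opt = None
        for r in range(1, len(initial) + 1):
            for combo in itertools.combinations(initial, r):
                covered = set()
                for _, ms in combo:
                    covered |= ms.cover
                if covered >= total:
                    opt = r
                    break
            if opt:
                break
        assert len(final) <= math.ceil(math.log(len(initial)) + 1) * opt


@pytest.fixture(scope="module")
def small_index():
    p = ScoringParams(max_ins=1, max_del=1)
    t = generate_target(24, model="pa", density=2.4, seed=5)
    sim = identity_similarity(t)
    ix = build_index(t, sim, p, k=4, eta=60, cutoff=3.0, seed=11, n_null=200)
    return t, sim, p, ix


class TestBuildIndex:
    def test_coverage_goal_met_and_final_subset_of_initial(self, small_index):
        t, _, _, ix = small_index
        assert ix.coverage_met
        assert len(ix.cover_nodes) >= 0.60 * t.n_nodes
        assert ix.n_references <= ix.initial_size

    def test_mappings_disjoint_and_significant(self, small_index):
        _, _, _, ix = small_index
        for _, mset in ix.references:
            mset.validate(cutoff=ix.params["cutoff"])

    def test_initial_set_coverage_monotone(self):
        p = ScoringParams(max_ins=1, max_del=1)
        t = generate_target(24, model="pa", density=2.4, seed=5)
        sim = identity_similarity(t)
        initial, reached = build_initial_set(t, sim, p, k=4, eta=50, cutoff=3.0,
                                             seed=1, n_null=200)
        assert reached
        covered = set()
        sizes = []
        for _, mset in initial:
            covered |= mset.cover
            sizes.append(len(covered))
        assert sizes == sorted(sizes)
        # the loop stops at the first reference reaching the goal
        assert sizes[-1] >= 0.5 * t.n_nodes
        if len(sizes) > 1:
            assert sizes[-2] < 0.5 * t.n_nodes

    def test_cap_reported_when_eta_unreachable(self, caplog):
        p = ScoringParams(max_ins=1, max_del=1)
        t = generate_target(20, model="pa", density=2.0, seed=3)
        with caplog.at_level("WARNING", logger="netquery"):
            initial, reached = build_initial_set(
                t, SimilarityMatrix(), p, k=4, eta=90, cutoff=3.0, seed=1,
                n_null=200, max_references=3,
            )
        assert not reached and len(initial) == 3


class TestIndexSerialization:
    def test_round_trip_preserves_everything(self, small_index, tmp_path):
        t, _, _, ix = small_index
        path = tmp_path / "ix.json"
        save_index(ix, path)
        ix2 = load_index(path, t)
        assert ix2.target_checksum == ix.target_checksum
        assert ix2.params == ix.params
        assert ix2.initial_size == ix.initial_size
        assert ix2.cover_nodes == ix.cover_nodes
        assert len(ix2.references) == len(ix.references)
        for (r1, m1), (r2, m2) in zip(ix.references, ix2.references):
            assert r1.tree == r2.tree and m1 == m2

    def test_stale_index_rejected(self, small_index, tmp_path):
        t, _, _, ix = small_index
        path = tmp_path / "ix.json"
        save_index(ix, path)
        other = generate_target(24, model="pa", density=2.4, seed=99)
        with pytest.raises(StaleIndexError):
            load_index(path, other)

    def test_malformed_json_rejected(self, small_index, tmp_path):
        t, _, _, _ = small_index
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ValidationError):
            load_index(path, t)

    def test_rebuild_is_byte_identical(self, small_index, tmp_path):
        t, sim, p, ix = small_index
        ix2 = build_index(t, sim, p, k=4, eta=60, cutoff=3.0, seed=11, n_null=200)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_index(ix, p1)
        save_index(ix2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_checksum_is_order_independent_and_weight_sensitive(self):
        a = Network("a", ["x", "y"], [("x", "y", 0.5)])
        b = Network("b", ["y", "x"], [("y", "x", 0.5)])
        c = Network("c", ["x", "y"], [("x", "y", 0.6)])
        assert network_checksum(a) == network_checksum(b)
        assert network_checksum(a) != network_checksum(c)
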