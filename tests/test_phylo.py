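import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _bfs_oracle import all_pairs_bfs, joint_bfs_distance
from scnakit.events import EventRecord, apply_events, diploid_profile
from scnakit.genome import make_bins
from scnakit.phylo import (
    classify_events,
    clone_ancestor_map,
    interval_event_distance,
    min_interval_events,
    min_interval_events_matrix,
    reconstruct_tree,
)
from scnakit.simulate import simulate_clonal_truth


def _profile(bins, hap_a, hap_b=None):
    cn = np.ones((bins.n_bins, 2), dtype=np.int64)
    cn[:, 0] = hap_a
    cn[:, 1] = hap_b if hap_b is not None else 1
    return cn


class TestIntervalEventDistance:
    def test_identity(self, small_bins):
        p = diploid_profile(small_bins)
        count, events = interval_event_distance(p, p, small_bins)
        assert count == 0 and events == []

    def test_single_gain_interval(self):
        bins = make_bins({"chr1": 5_000_000}, 1_000_000)
        parent = _profile(bins, [1, 1, 1, 1, 1])
        child = _profile(bins, [1, 2, 2, 2, 1])
        count, events = interval_event_distance(parent, child, bins)
        assert count == 1
        ev = events[0]
        assert (ev.kind, ev.haplotype, ev.start_bin, ev.end_bin, ev.delta) == \
            ("gain", "A", 1, 4, 1)

    def test_nested_gains_cost_two(self):
        bins = make_bins({"chr1": 3_000_000}, 1_000_000)
        parent = _profile(bins, [1, 1, 1])
        child = _profile(bins, [2, 3, 2])
        count, _ = interval_event_distance(parent, child, bins)
        assert count == 2

    def test_loh_irreversibility_raises(self):
        bins = make_bins({"chr1": 1_000_000}, 1_000_000)
        parent = np.array([[0, 1]])
        child = np.array([[1, 1]])
        with pytest.raises(ValueError, match="no valid event path"):
            interval_event_distance(parent, child, bins)

    def test_events_do_not_cross_chromosomes(self, two_chrom_bins):
        parent = diploid_profile(two_chrom_bins)
        child = parent.copy()
        child[:, 0] += 1  # +1 on every bin of both chromosomes
        count, events = interval_event_distance(parent, child, two_chrom_bins)
        assert count == 2
        assert {e.chrom for e in events} == {"chr1", "chr2"}

    def test_wgd_costs_one_event(self, small_bins):
        p = diploid_profile(small_bins)
        count, events = interval_event_distance(p, p * 2, small_bins, allow_wgd=True)
        assert count == 1
        assert events[0].kind == "wgd"

    def test_wgd_after_interval_events(self, small_bins):
        # child = 2 * (parent with one deletion): WGD-last is cheaper
        p = diploid_profile(small_bins)
        pre = p.copy()
        pre[0:3, 1] = 0
        child = pre * 2
        count, events = interval_event_distance(p, child, small_bins, allow_wgd=True)
        assert count == 2
        kinds = [e.kind for e in events]
        assert "wgd" in kinds

    def test_replay_reconstructs_child(self, rng):
        bins = make_bins({"chr1": 6_000_000, "chr2": 4_000_000}, 1_000_000)
        for _ in range(50):
            parent = rng.integers(0, 4, size=(10, 2))
            delta = rng.integers(-2, 3, size=(10, 2))
            child = np.maximum(parent + delta, 0)
            child[parent == 0] = 0  # respect irreversibility
            count, events = interval_event_distance(parent, child, bins)
            assert np.array_equal(apply_events(parent, events, check=False), child)
            assert count == len([e for e in events if not e.is_wgd()])


class TestOracleAgreement:
    """The analytic distance must equal BFS shortest paths on the event
    graph (small regime; the full sweep lives in the acceptance suite)."""

    def test_exhaustive_3bin_cn2(self):
        bins = make_bins({"chr1": 3_000_000}, 1_000_000)
        states, dist = all_pairs_bfs(3, 2)
        analytic = min_interval_events_matrix(states, states)
        assert np.array_equal(np.isinf(analytic), np.isinf(dist))
        finite = ~np.isinf(dist)
        assert np.array_equal(analytic[finite], dist[finite])

    def test_scalar_path_agrees_with_batch(self, rng):
        states = rng.integers(0, 4, size=(40, 5))
        batch = min_interval_events_matrix(states, states)
        for i in range(0, 40, 7):
            for j in range(0, 40, 7):
                assert min_interval_events(states[i], states[j]) == batch[i, j]

    def test_joint_distance_is_sum_of_haplotype_distances(self, rng):
        bins = make_bins({"chr1": 4_000_000}, 1_000_000)
        for _ in range(15):
            parent = rng.integers(0, 3, size=(4, 2))
            child = rng.integers(0, 3, size=(4, 2))
            per_hap = sum(
                min_interval_events(parent[:, h], child[:, h]) for h in (0, 1)
            )
            joint = joint_bfs_distance(parent, child, max_cn=2)
            if np.isinf(per_hap):
                assert joint is None
            else:
                assert joint == per_hap


class TestClassifyEvents:
    def test_loh(self):
        bins = make_bins({"chr1": 3_000_000}, 1_000_000)
        parent = diploid_profile(bins)
        events = [EventRecord(None, "B", "chr1", 0, 2, -1)]
        out = classify_events(events, parent)
        assert out[0].kind == "loh"

    def test_cn_loh_joint_classification(self):
        # (1,1) -> (0,2): the loss is a copy-neutral LOH once the retained
        # allele is amplified over the same interval
        bins = make_bins({"chr1": 3_000_000}, 1_000_000)
        parent = diploid_profile(bins)
        events = [
            EventRecord(None, "A", "chr1", 0, 2, -1),
            EventRecord(None, "B", "chr1", 0, 2, 1),
        ]
        kinds = {e.kind for e in classify_events(events, parent)}
        assert kinds == {"cn_loh", "gain"}

    def test_del_when_copies_remain(self):
        bins = make_bins({"chr1": 2_000_000}, 1_000_000)
        parent = np.array([[2, 1], [2, 1]])
        events = [EventRecord(None, "A", "chr1", 0, 2, -1)]
        assert classify_events(events, parent)[0].kind == "del"


class TestReconstructTree:
    def test_single_clone_truncal_edge(self, small_bins):
        clone = diploid_profile(small_bins)
        clone[0:4, 0] += 1
        clone[6:8, 1] = 0
        tree = reconstruct_tree([("c1", clone)], small_bins, allow_wgd=False)
        assert set(tree.nodes) == {"diploid", "c1"}
        assert tree.total_events == 2
        assert np.all(tree.nodes["diploid"] == 1)

    def test_shared_ancestor_recovered(self, small_bins):
        anc = diploid_profile(small_bins)
        anc[0:5, 0] += 1  # truncal gain
        c1 = anc.copy()
        c1[6:8, 1] = 0
        c2 = anc.copy()
        c2[8:10, 0] += 1
        tree = reconstruct_tree([("c1", c1), ("c2", c2)], small_bins, allow_wgd=False)
        assert tree.total_events == 3
        internal = [n for n in tree.nodes if n.startswith("anc")]
        assert len(internal) == 1
        assert np.array_equal(tree.nodes[internal[0]], anc)

    def test_chain_truth_topology_recovered(self, genome_bins):
        truth = simulate_clonal_truth(
            genome_bins, n_clones=4, n_truncal_events=10, n_private_events=2,
            p_wgd=0.0, deletion_bias=0.5, seed=13, topology="chain",
            min_event_bins=2)
        clones = [(cid, truth.clone_profiles[cid]) for cid in truth.clone_ids]
        tree = reconstruct_tree(clones, genome_bins, allow_wgd=False)
        recovered = clone_ancestor_map(tree, truth.clone_ids)
        assert recovered == truth.parent

    def test_extra_private_event_adds_one(self, small_bins):
        anc = diploid_profile(small_bins)
        anc[0:5, 0] += 1
        c1 = anc.copy()
        c1[6:8, 1] = 0
        tree1 = reconstruct_tree([("c1", c1)], small_bins, allow_wgd=False)
        c1b = c1.copy()
        c1b[9, 0] += 1  # disjoint from existing segments
        tree2 = reconstruct_tree([("c1", c1b)], small_bins, allow_wgd=False)
        assert tree2.total_events == tree1.total_events + 1

    def test_edge_replay_on_random_reconstructions(self, genome_bins):
        for seed in range(5):
            truth = simulate_clonal_truth(
                genome_bins, n_clones=3, n_truncal_events=8, n_private_events=3,
                p_wgd=0.5, deletion_bias=0.6, seed=seed, min_event_bins=2)
            clones = [(cid, truth.clone_profiles[cid]) for cid in truth.clone_ids]
            tree = reconstruct_tree(clones, genome_bins, allow_wgd=True)
            tree.validate_replay()  # raises on mismatch
            assert np.all(tree.nodes[tree.root] == 1)
            for cid in truth.clone_ids:
                assert cid in tree.leaves()

    def test_wgd_subclone_edge(self, small_bins):
        base = diploid_profile(small_bins)
        base[0:3, 1] = 0
        doubled = base * 2
        tree = reconstruct_tree([("c1", base), ("c2", doubled)], small_bins,
                                allow_wgd=True)
        # the doubled clone is reached by one WGD from the undoubled state
        edge_kinds = {c: [e.kind for e in evs] for _, c, evs, _ in tree.edges}
        assert edge_kinds["c2"] == ["wgd"] or "wgd" in edge_kinds["c2"]

    def test_too_many_clones_errors(self, small_bins):
        clones = [(f"c{i}", diploid_profile(small_bins)) for i in range(9)]
        with pytest.raises(ValueError, match="greedy"):
            reconstruct_tree(clones, small_bins, method="exhaustive")

    def test_greedy_mode_on_chain(self, genome_bins):
        truth = simulate_clonal_truth(
            genome_bins, n_clones=4, n_truncal_events=8, n_private_events=2,
            p_wgd=0.0, deletion_bias=0.5, seed=3, topology="chain",
            min_event_bins=2)
        clones = [(cid, truth.clone_profiles[cid]) for cid in truth.clone_ids]
        tree = reconstruct_tree(clones, genome_bins, method="greedy")
        tree.validate_replay()
        assert {c for _, c, _, _ in tree.edges} == set(truth.clone_ids)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_distance_decomposition_replays(seed):
    """Property: the optimal event list always replays parent -> child."""
    bins = make_bins({"chr1": 5_000_000, "chr2": 3_000_000}, 1_000_000)
    rng = np.random.default_rng(seed)
    parent = rng.integers(0, 4, size=(8, 2))
    child = rng.integers(0, 4, size=(8, 2))
    child[parent == 0] = 0
    count, events = interval_event_distance(parent, child, bins)
    assert np.array_equal(apply_events(parent, events, check=False), child)
    assert count == len(events)
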