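"""Adjacency classification, grouping, foldbacks and reciprocal
configurations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brfscan import Breakpoint, classify_adjacency, detect_foldbacks, find_reciprocal, make_junction
from brfscan.adjacency import (
    CLASS_GAPPED,
    CLASS_INSERTION_OVERLAP,
    CLASS_PARALLEL,
    KIND_NESTED_DELETIONS,
    KIND_RECIPROCAL_FOLDBACKS,
)

from conftest import random_catalog
from oracles import brute_force_adjacency, catalog_to_oracle_form


def bp(pos, orient, jid="j", chrom="chr1"):
    return Breakpoint(chrom, pos, orient, "s", jid)


class TestClassification:
    def test_resection_scale_parallel_pair(self):
        # two parallel breakpoints 429 bp apart (resection-scale offset)
        cat = classify_adjacency([bp(50_762_606, "R", "a"), bp(50_763_035, "R", "b")])
        (pair,) = cat.pairs
        assert pair.cls == CLASS_PARALLEL
        assert pair.distance == 429
        assert not pair.flush

    def test_deletion_sliver_is_gapped(self):
        cat = classify_adjacency([bp(1000, "L", "a"), bp(1500, "R", "b")])
        (pair,) = cat.pairs
        assert pair.cls == CLASS_GAPPED and pair.distance == 500

    def test_beyond_threshold_no_pair(self):
        cat = classify_adjacency([bp(1000, "R", "a"), bp(26_000, "R", "b")], threshold=20_000)
        assert cat.pairs == []

    def test_insertion_overlap_consumes_before_parallel(self):
        """An L breakpoint between two R breakpoints is consumed by the
        nearest-first insertion/overlap stage; the survivors still form a
        parallel pair."""
        cat = classify_adjacency([bp(1000, "R", "a"), bp(1400, "L", "b"), bp(1800, "R", "c")])
        by_class = {p.cls: p for p in cat.pairs}
        io = by_class[CLASS_INSERTION_OVERLAP]
        assert (io.bp_a.pos, io.bp_b.pos) == (1000, 1400)
        assert all(bp.pos in (1800,) or bp.orient == "R" for bp in cat.surviving)

    def test_no_breakpoint_in_two_classes_after_exclusion(self, default_sim):
        cat = classify_adjacency(default_sim.breakpoints)
        io_members = {
            id(b) for p in cat.pairs_of(CLASS_INSERTION_OVERLAP) for b in (p.bp_a, p.bp_b)
        }
        other_members = {
            id(b)
            for p in cat.pairs
            if p.cls != CLASS_INSERTION_OVERLAP
            for b in (p.bp_a, p.bp_b)
        }
        assert not io_members & other_members

    def test_flush_pair_retained_with_flag(self):
        cat = classify_adjacency([bp(5000, "L", "a"), bp(5000, "L", "b")])
        (pair,) = cat.pairs
        assert pair.cls == CLASS_PARALLEL and pair.flush and pair.distance == 0

    def test_three_member_run_groups_single_linkage(self):
        cat = classify_adjacency([bp(1000, "R", "a"), bp(9000, "R", "b"), bp(17_000, "R", "c")],
                                 threshold=10_000)
        (group,) = cat.groups
        assert [m.pos for m in group.members] == [1000, 9000, 17_000]
        assert [p.distance for p in cat.pairs_of(CLASS_PARALLEL)] == [8000, 8000]

    def test_unoriented_breakpoints_skipped_and_counted(self):
        cat = classify_adjacency([bp(1000, "R"), Breakpoint("chr1", 1200, None, "s", "x")])
        assert cat.skipped_unoriented == 1
        assert cat.counts["breakpoints"] == 1

    @pytest.mark.parametrize("n_catalogs,n_max", [(20, 120)])
    def test_equivalent_to_brute_force_oracle(self, n_catalogs, n_max):
        rng = np.random.default_rng(2024)
        for _ in range(n_catalogs):
            bps = random_catalog(rng, int(rng.integers(2, n_max)))
            cat = classify_adjacency(bps, 20_000)
            assert catalog_to_oracle_form(cat) == brute_force_adjacency(bps, 20_000)

    @given(st.lists(st.integers(min_value=1, max_value=500_000), min_size=2, max_size=40),
           st.sampled_from(["L", "R"]))
    def test_parallel_pairs_monotone_in_threshold_without_interference(self, positions, orient):
        """With a single orientation present (no exclusion interference),
        the pair set at threshold T is a subset of the set at T' > T."""
        bps = [bp(p, orient, f"j{i}") for i, p in enumerate(positions)]
        small = {p.key for p in classify_adjacency(bps, 5_000).pairs}
        large = {p.key for p in classify_adjacency(bps, 50_000).pairs}
        assert small <= large


class TestFoldbacks:
    def test_same_orientation_short_junction_is_foldback(self):
        j = make_junction("fb", bp(39_713_480, "R", "fb", "chr17"),
                          bp(39_714_939, "R", "fb", "chr17"))
        ((junc, d, orient),) = detect_foldbacks([j])
        assert d == 1_459 and orient == "R"

    def test_interchromosomal_not_foldback(self):
        j = make_junction("t", bp(1000, "R", "t", "chr1"), bp(1000, "R", "t", "chr2"))
        assert detect_foldbacks([j]) == []

    def test_deletion_junction_not_foldback(self):
        j = make_junction("d", bp(1000, "L", "d"), bp(2000, "R", "d"))
        assert detect_foldbacks([j]) == []

    def test_long_span_same_orientation_not_foldback(self):
        j = make_junction("x", bp(1000, "R", "x"), bp(500_000, "R", "x"))
        assert detect_foldbacks([j], threshold=20_000) == []


class TestReciprocal:
    def test_nested_deletions(self):
        outer = make_junction("d1", bp(10_000, "L", "d1"), bp(15_000, "R", "d1"))
        inner = make_junction("d2", bp(10_400, "L", "d2"), bp(14_500, "R", "d2"))
        junctions = [outer, inner]
        cat = classify_adjacency([b for j in junctions for b in j.breakpoints])
        configs = find_reciprocal(cat, junctions)
        full = [c for c in configs if not c.partial]
        assert full and all(c.kind == KIND_NESTED_DELETIONS for c in full)

    def test_reciprocal_foldbacks(self):
        left = make_junction("f1", bp(9_500, "L", "f1"), bp(10_000, "L", "f1"))
        right = make_junction("f2", bp(10_001, "R", "f2"), bp(10_600, "R", "f2"))
        junctions = [left, right]
        cat = classify_adjacency([b for j in junctions for b in j.breakpoints])
        configs = [c for c in find_reciprocal(cat, junctions) if not c.partial]
        assert configs and configs[0].kind == KIND_RECIPROCAL_FOLDBACKS
        inner = configs[0].gapped_pair
        assert (inner.bp_a.pos, inner.bp_b.pos) == (10_000, 10_001)

    def test_lone_parallel_pair_not_reported(self):
        cat = classify_adjacency([bp(1000, "R", "a"), bp(1500, "R", "b")])
        assert find_reciprocal(cat) == []


class TestSimulatorRecovery:
    def test_noise_free_run_recovers_every_sister_pair(self, clean_sim):
        cat = classify_adjacency(clean_sim.breakpoints)
        detected = {
            (p.bp_a.pos, p.bp_b.pos, p.bp_a.orient) for p in cat.pairs_of(CLASS_PARALLEL)
        }
        for t in clean_sim.truth["sister_pairs"]:
            assert (t["pos_a"], t["pos_b"], t["orient"]) in detected

    def test_noise_free_g1_ligations_all_yield_gapped_pairs(self):
        from brfscan import SimConfig, simulate

        out = simulate(SimConfig(seed=3, p_brf=0.0, nick_prob=0.0, min_dsb_spacing=50_000))
        cat = classify_adjacency(out.breakpoints)
        assert cat.counts[CLASS_PARALLEL] == 0
        assert cat.counts[CLASS_INSERTION_OVERLAP] == 0
        gapped = {(p.bp_a.pos, p.bp_b.pos) for p in cat.pairs_of(CLASS_GAPPED)}
        truth = {(t["pos_a"], t["pos_b"]) for t in out.truth["g1_gapped_pairs"]}
        assert truth <= gapped
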