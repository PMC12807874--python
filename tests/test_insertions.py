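"""Insertion extraction, origin tiling, chains and strand concordance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brfscan import (
    Breakpoint,
    Insertion,
    SimConfig,
    assemble_chains,
    classify_adjacency,
    detect_tiles,
    extract_insertions,
    make_junction,
    simulate,
    strand_concordance,
)
from brfscan.insertions import (
    VERDICT_COMPATIBLE,
    VERDICT_INCOMPATIBLE,
    VERDICT_INDETERMINATE,
)


def bp(pos, orient, jid="j", chrom="chr1"):
    return Breakpoint(chrom, pos, orient, "s", jid)


def ins(jid, idx, start, end, strand="fwd"):
    return Insertion(jid, idx, "chr1", start, end, strand, end - start + 1)


class TestExtraction:
    def test_catalog_RL_pair_becomes_candidate_insertion(self):
        cat = classify_adjacency([bp(10_000, "R", "a"), bp(11_999, "L", "b")])
        out = extract_insertions([], cat, max_span=10_000)
        (candidate,) = out
        assert candidate.length == 2_000
        assert (candidate.origin_start, candidate.origin_end) == (10_000, 11_999)

    def test_pair_beyond_ceiling_not_a_candidate(self):
        cat = classify_adjacency([bp(10_000, "R", "a"), bp(25_000, "L", "b")], threshold=20_000)
        assert extract_insertions([], cat, max_span=10_000) == []

    def test_junction_fragments_annotated_with_nearest_breakpoint(self):
        frag = ins("j1", 1, 36_130_000, 36_130_183)
        j1 = make_junction("j1", bp(1_000, "R", "j1"), bp(900_000, "L", "j1"),
                           inserted_fragments=[frag])
        j2 = make_junction("j2", bp(36_131_000, "R", "j2"), bp(50_000_000, "L", "j2"))
        (out,) = [i for i in extract_insertions([j1, j2]) if i.has_origin]
        assert out.nearest_ancestral_bp == (817, "j2")

    def test_junction_without_fragments_or_RL_pair_yields_nothing(self):
        j = make_junction("j", bp(1_000, "L", "j"), bp(2_000, "R", "j"))
        assert extract_insertions([j]) == []


class TestTiles:
    def test_nine_cotiling_insertions_across_junctions_form_one_tile(self):
        members = []
        start = 36_130_000
        for i in range(9):
            length = 150 + 10 * i
            members.append(ins(f"c{i % 6}", 1, start, start + length - 1))
            start += length + 20  # small gaps
        (tile,) = detect_tiles(members)
        assert len(tile.members) == 9
        assert tile.frac_small_gap == 1.0
        assert tile.frac_overlap == 0.0
        assert {m.dest_junction_id for m in tile.members} == {f"c{i}" for i in range(6)}

    def test_three_members_below_minimum_no_tile(self):
        members = [ins("a", 1, 1000, 1200), ins("b", 1, 1230, 1400), ins("c", 1, 1420, 1600)]
        assert detect_tiles(members, min_members=4) == []

    def test_gap_overlap_vector_is_signed(self):
        members = [ins("a", 1, 1000, 1199), ins("b", 1, 1230, 1399), ins("c", 1, 1380, 1500),
                   ins("d", 1, 1530, 1650)]
        (tile,) = detect_tiles(members)
        assert tile.gaps == (30, -20, 29)

    def test_adjacent_breakpoint_side_and_inferred_strand(self):
        members = [ins(f"c{i}", 1, 10_000 + 210 * i, 10_180 + 210 * i, "unknown")
                   for i in range(5)]
        tile_bps = [bp(9_900, "R", "x")]
        (tile,) = detect_tiles(members, breakpoints=tile_bps)
        assert tile.adjacent_breakpoint[1] == "left"
        assert tile.inferred_strand == "fwd"
        # explicit strands are never overwritten
        assert all(m.origin_strand == "unknown" for m in tile.members)


class TestChains:
    def test_three_insertions_make_two_consecutive_pairs(self):
        j = make_junction("j", bp(1000, "R", "j"), bp(2000, "L", "j"),
                          inserted_fragments=[ins("j", 1, 10, 100),
                                              ins("j", 2, 200, 300, "rev"),
                                              ins("j", 3, 400, 500)])
        (chain,) = assemble_chains([j])
        assert chain.informative_pairs == 2
        assert (chain.same_strand_pairs, chain.opposite_strand_pairs) == (0, 2)
        assert chain.strand_pattern == "><>"

    def test_single_insertion_is_not_a_chain(self):
        j = make_junction("j", bp(1000, "R", "j"), bp(2000, "L", "j"),
                          inserted_fragments=[ins("j", 1, 10, 100)])
        assert assemble_chains([j]) == []

    def test_unknown_strands_skipped_pairwise(self):
        j = make_junction("j", bp(1000, "R", "j"), bp(2000, "L", "j"),
                          inserted_fragments=[ins("j", 1, 10, 100),
                                              ins("j", 2, 200, 300, "unknown"),
                                              ins("j", 3, 400, 500)])
        (chain,) = assemble_chains([j])
        assert chain.informative_pairs == 0

    @given(st.lists(st.sampled_from(["fwd", "rev", "unknown"]), min_size=2, max_size=12))
    def test_pair_count_conservation(self, strands):
        frags = [ins("j", i + 1, 100 * i + 1, 100 * i + 50, s) for i, s in enumerate(strands)]
        j = make_junction("j", bp(1000, "R", "j"), bp(2000, "L", "j"),
                          inserted_fragments=frags)
        (chain,) = assemble_chains([j])
        known_pairs = sum(
            1 for a, b in zip(strands, strands[1:]) if "unknown" not in (a, b)
        )
        assert chain.same_strand_pairs + chain.opposite_strand_pairs == known_pairs


class TestStrandConcordance:
    def test_all_forward_is_mmbir_compatible(self):
        frags = [ins("j", i, 100 * i + 1, 100 * i + 50) for i in range(1, 5)]
        j = make_junction("j", bp(1000, "R", "j"), bp(2000, "L", "j"),
                          inserted_fragments=frags)
        verdict = strand_concordance(assemble_chains([j]))
        assert verdict["verdict"] == VERDICT_COMPATIBLE
        assert (verdict["same"], verdict["opposite"]) == (3, 0)

    def test_no_informative_pairs_is_indeterminate(self):
        assert strand_concordance([])["verdict"] == VERDICT_INDETERMINATE

    def test_simulator_chain_count_matches_truth(self, default_sim):
        chains = assemble_chains(default_sim.junctions)
        assert len(chains) == len(default_sim.truth["chains"])

    def test_mmbir_mode_never_violates_strand_coordination(self, mmbir_sim):
        verdict = strand_concordance(assemble_chains(mmbir_sim.junctions))
        assert verdict["opposite"] == 0
        assert verdict["verdict"] == VERDICT_COMPATIBLE

    def test_brf_mode_violates_strand_coordination(self, default_sim):
        verdict = strand_concordance(assemble_chains(default_sim.junctions))
        assert verdict["opposite"] > 0
        assert verdict["verdict"] == VERDICT_INCOMPATIBLE


class TestModeContrast:
    def test_mmbir_origins_scatter_but_brf_origins_tile(self, default_sim, mmbir_sim):
        brf_tiles = detect_tiles([i for j in default_sim.junctions for i in j.inserted_fragments])
        mmbir_tiles = detect_tiles([i for j in mmbir_sim.junctions for i in j.inserted_fragments])
        assert len(brf_tiles) >= 1
        assert mmbir_tiles == []

    def test_mmbir_origin_overlaps_are_material(self, mmbir_sim):
        gaps = []
        for j in mmbir_sim.junctions:
            members = sorted(j.inserted_fragments, key=lambda i: i.origin_start)
            gaps += [b.origin_start - a.origin_end - 1 for a, b in zip(members, members[1:])]
        frac_overlap = np.mean([g <= -10 for g in gaps])
        assert frac_overlap >= 0.1

    def test_brf_origin_overlaps_are_rare(self, default_sim):
        tiles = detect_tiles([i for j in default_sim.junctions for i in j.inserted_fragments])
        assert all(t.frac_overlap < 0.05 for t in tiles)
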