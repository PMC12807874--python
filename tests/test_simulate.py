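"""Simulator contracts: determinism, phase structure, conservation and
amplification modes."""

import filecmp

import numpy as np
import pytest

from brfscan import (
    SimConfig,
    assemble_chains,
    classify_adjacency,
    detect_foldbacks,
    simulate,
    simulate_amplification,
)
from brfscan.adjacency import CLASS_PARALLEL


def coverage_from_truth(truth, genome_length):
    """Independent re-derivation of the rearranged-haplotype coverage from
    the truth segment list (difference-array sweep)."""
    delta = np.zeros(genome_length + 2, dtype=int)
    for seg in truth["retained_segments"]:
        delta[seg["start"]] += 1
        delta[seg["end"] + 1] -= 1
    return np.cumsum(delta)[1 : genome_length + 1]


class TestDeterminism:
    def test_identical_config_and_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            simulate(SimConfig(seed=17)).write(tmp_path / d)
        for name in ("junctions.bedpe", "cn.bed", "substitutions.vcf",
                     "insertions.tsv", "truth.json"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)

    def test_different_seeds_differ(self):
        a = simulate(SimConfig(seed=1))
        b = simulate(SimConfig(seed=2))
        assert a.breakpoints != b.breakpoints


class TestShattering:
    def test_zero_dsbs_leaves_chromosome_intact(self):
        out = simulate(SimConfig(seed=5, mean_dsbs=0.0, nick_prob=0.0))
        assert out.junctions == []
        assert out.truth["sister_pairs"] == [] and out.truth["substitutions"] == []
        # the intact chromatid survives as the single retained molecule
        (seg,) = [s for s in out.cn_profile.all_segments() if s.haplotype == "A"]
        assert (seg.start, seg.end, seg.copy) == (1, 50_000_000, 1)

    def test_resection_cap_bounds_every_sister_offset(self):
        for seed in (1, 2, 3):
            out = simulate(SimConfig(seed=seed))
            assert all(t["offset"] <= 20_000 for t in out.truth["sister_pairs"])

    def test_offsets_are_resection_scale(self, default_sim):
        offsets = [t["offset"] for t in default_sim.truth["sister_pairs"] if t["offset"]]
        assert 100 <= np.median(offsets) <= 3_000


class TestPhaseContracts:
    def test_all_g1_run_has_no_parallel_pairs_and_no_chains(self):
        out = simulate(SimConfig(seed=3, p_brf=0.0, nick_prob=0.0))
        cat = classify_adjacency(out.breakpoints)
        assert cat.counts[CLASS_PARALLEL] == 0
        assert assemble_chains(out.junctions) == []
        assert out.truth["sister_pairs"] == []

    def test_all_sg2_with_certain_foldback_every_junction_folds_back(self):
        out = simulate(SimConfig(seed=3, p_brf=1.0, p_foldback=1.0, nick_prob=0.0))
        assert len(out.junctions) > 0
        assert len(detect_foldbacks(out.junctions)) == len(out.junctions)

    def test_insertion_chains_only_at_sg2_junctions(self, default_sim):
        phases = {r["junction_id"]: r["phase"] for r in default_sim.truth["breakpoints"]}
        for j in default_sim.junctions:
            if j.inserted_fragments:
                assert phases[j.id] == "S-G2"


class TestConservation:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_cn_profile_equals_homolog_plus_retained_segments(self, seed):
        out = simulate(SimConfig(seed=seed))
        expected = coverage_from_truth(out.truth, out.config.genome_length)
        for seg in out.cn_profile.all_segments():
            if seg.haplotype != "A":
                continue
            block = expected[seg.start - 1 : seg.end]
            assert (block == seg.copy).all(), (seg.start, seg.end, seg.copy)

    def test_sister_partnering_is_mutual_and_within_cap(self, default_sim):
        for t in default_sim.truth["sister_pairs"]:
            assert 0 <= t["pos_b"] - t["pos_a"] == t["offset"] <= 20_000


class TestAmplification:
    def test_linear_inverted_doubles_per_generation(self):
        out = simulate_amplification(SimConfig(seed=5), mode="linear_inverted", generations=4)
        assert out.truth["amplicon_copy"] == 16
        plateau = max(s.copy for s in out.cn_profile.all_segments() if s.haplotype == "A")
        assert plateau == 16
        assert len(detect_foldbacks(out.junctions)) == len(out.junctions) == 4

    def test_linear_inverted_breakpoints_confined_to_amplicon(self):
        cfg = SimConfig(seed=8)
        out = simulate_amplification(cfg, mode="linear_inverted", generations=5)
        for j in out.junctions:
            for bp in j.breakpoints:
                assert cfg.fragment_start <= bp.pos <= cfg.fragment_end

    def test_episome_ii_has_two_opposite_foldbacks_at_fragment_ends(self):
        cfg = SimConfig(seed=5)
        out = simulate_amplification(cfg, mode="episome_II", generations=3)
        fbs = detect_foldbacks(out.junctions)
        assert len(fbs) == len(out.junctions) == 2
        assert {orient for _, _, orient in fbs} == {"L", "R"}
        positions = sorted(bp.pos for j in out.junctions for bp in j.breakpoints)
        assert positions[0] == cfg.fragment_start and positions[-1] == cfg.fragment_end

    def test_episome_i_single_head_to_tail_junction(self):
        cfg = SimConfig(seed=5)
        out = simulate_amplification(cfg, mode="episome_I", generations=4)
        (j,) = out.junctions
        assert (j.bp1.orient, j.bp2.orient) == ("R", "L")
        assert (j.bp1.pos, j.bp2.pos) == (cfg.fragment_start, cfg.fragment_end)
        assert out.truth["amplicon_copy"] >= 1

    def test_clustered_foldback_independence_probability_is_tiny(self):
        """Foldbacks piled near one amplicon edge after several rounds:
        under independent breakage their co-occurrence probability is at
        the (10 kb / amplicon)^k scale."""
        from brfscan import IndependenceQuery, independence_probability

        cfg = SimConfig(seed=8)
        out = simulate_amplification(cfg, mode="linear_inverted", generations=3)
        amplicon = cfg.fragment_end - cfg.fragment_start
        left_edge = [
            j for j in out.junctions if j.bp1.pos - cfg.fragment_start < 20_000
        ]
        assert len(left_edge) >= 2
        span = max(j.bp2.pos for j in left_edge) - min(j.bp1.pos for j in left_edge)
        p = independence_probability(
            IndependenceQuery(max(span, 1), amplicon, k=len(left_edge) - 1)
        ).p_indep
        assert p < 0.01

    def test_generation_overflow_truncated(self, caplog):
        cfg = SimConfig(seed=5, copy_cap=16)
        with caplog.at_level("WARNING"):
            out = simulate_amplification(cfg, mode="linear_inverted", generations=10)
        assert out.truth["amplicon_copy"] == 16
        assert "truncated" in caplog.text


class TestMmbirMode:
    def test_duplication_overlap_contrast_between_modes(self, default_sim, mmbir_sim):
        def overlap_fraction(sim):
            gaps = []
            for j in sim.junctions:
                ms = sorted(j.inserted_fragments, key=lambda i: i.origin_start or 0)
                ms = [m for m in ms if m.has_origin]
                gaps += [b.origin_start - a.origin_end - 1 for a, b in zip(ms, ms[1:])]
            return np.mean([g <= -10 for g in gaps]) if gaps else 0.0

        assert overlap_fraction(mmbir_sim) >= 0.1
        assert overlap_fraction(default_sim) < 0.05

    def test_mmbir_chains_are_single_stranded(self, mmbir_sim):
        for j in mmbir_sim.junctions:
            strands = {i.origin_strand for i in j.inserted_fragments}
            assert len(strands) == 1
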