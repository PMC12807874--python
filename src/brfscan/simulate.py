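"""Mechanistic simulator of chromosome fragmentation followed by
breakage-fusion-replication (G1 ligation) and breakage-replication-fusion
(post-replication sister-end fusion), with template-switching (MMBIR) and
segmental-amplification modes.

The generative model, in the order events occur:

1. *Shattering*: double-strand breaks placed uniformly on one chromatid;
   every break end receives a sampled 5'-resection length (log-normal,
   hard cap) that later becomes the offset between its two sister
   breakpoints.  Fragments may additionally carry single-strand gaps.
2. *G1 ligation*: a random subset of ends ligates before replication
   (classical NHEJ: <= 10 bp end trimming, <= 2 bp microhomology, no
   inserted fragments).  Ligated ends leave adjacent gapped breakpoints
   duplicated on both sisters.
3. *Replication*: every assembled fragment block is duplicated; each
   unligated end becomes two sister ends whose breakpoints are offset by
   the resection length — one derived from the ancestral 3' overhang
   (full length) and one from the recessed 5' strand.
4. *S/G2 fusion*: sister ends either fold back on each other (direct
   ligation, a foldback junction), join other free ends (microhomology-
   mediated, optionally with chains of short insertions copied from 3'
   overhangs in a tiling pattern), or stay unligated and are lost.
5. *Retention*: the largest assembled molecule (centromere proxy) plus a
   random subset of the others is retained; copy number is the intact
   homolog plus the retained sister-segment multiset.  APOBEC-style
   deamination is planted only inside retained overhang offsets, with the
   strand dictated by the side of the segment.

Every emitted breakpoint, insertion, substitution and segment is recorded
in a truth sidecar for validation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_model import (
    ORIENT_L,
    ORIENT_R,
    Breakpoint,
    CopyNumberProfile,
    CopyNumberSegment,
    Insertion,
    Junction,
    Substitution,
    make_junction,
    write_cn_segments,
    write_junctions,
    write_substitutions,
)

log = logging.getLogger(__name__)

SAMPLE_ID = "sim"

MODE_BRF = "brf"
MODE_MIXED = "mixed"
MODE_MMBIR = "mmbir"

AMP_NONE = "none"
AMP_EPISOME_I = "episome_I"
AMP_EPISOME_II = "episome_II"
AMP_LINEAR_INVERTED = "linear_inverted"


@dataclass
class SimConfig:
    """Study conditions for the synthetic-data generator.

    Defaults emulate a shattered ~50 Mb chromosome arm: resection offsets
    log-normal around a few hundred bp (printed examples are in the
    0.4-2 kb range) capped at 20 kb; insertion sizes log-normal with
    median 184 bp (subclone-resolved scale; `insertion_median=2000` for
    catalog-scale emulation); half of the break ends persisting into S
    phase.
    """

    chrom: str = "chrS"
    genome_length: int = 50_000_000
    mean_dsbs: float = 50.0
    # resection: log-normal with median 500 bp and sigma such that the
    # 97.5th percentile is ~5 kb; hard cap at the 20 kb adjacency scale
    resection_median: float = 500.0
    resection_sigma: float = 1.1746
    resection_cap: int = 20_000
    min_dsb_spacing: int = 0        # enforce a minimum break spacing (0 = none);
                                    # used for noise-free validation runs
    flush_prob: float = 0.15        # chance an end carries no offset at all
    nick_prob: float = 0.05         # single-strand gap per fragment
    p_brf: float = 0.5              # P(end persists into S phase)
    p_foldback: float = 0.3         # P(sister ends ligate to each other)
    p_unligated: float = 0.15       # P(a pooled sister end stays unfused)
    retain_acentric_prob: float = 0.5
    # insertions
    chain_len_mean: float = 1.5     # chain length = 1 + Poisson(mean)
    insertion_median: float = 184.0
    insertion_sigma: float = 0.6
    min_donor_overhang: int = 1_000
    max_tile_donors: int = 3
    tile_gap_mean: float = 15.0
    tile_gap_sd: float = 15.0
    distal_insertions_mean: float = 3.0
    strand_known_prob: float = 0.9
    # deamination
    deamination_prob: float = 0.6   # per retained overhang offset
    deamination_extra: float = 2.0  # cluster size = 3 + Poisson(extra)
    background_substitutions: float = 60.0
    # mmbir mode
    mmbir_chains: int = 40
    mmbir_synthesis_mean: float = 500.0
    mmbir_overlap_prob: float = 0.3
    # amplification mode
    amplification_mode: str = AMP_NONE
    generations: int = 4
    fragment_start: int = 20_000_000
    fragment_end: int = 20_500_000
    copy_cap: int = 256
    mode: str = MODE_MIXED
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown simulator config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimOutput:
    config: SimConfig
    junctions: list[Junction]
    cn_profile: CopyNumberProfile
    substitutions: list[Substitution]
    truth: dict

    @property
    def breakpoints(self) -> list[Breakpoint]:
        return [bp for j in self.junctions for bp in j.breakpoints]

    @property
    def insertions(self) -> list[Insertion]:
        return [ins for j in self.junctions for ins in j.inserted_fragments]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params = {"seed": self.config.seed, "mode": self.config.mode}
        write_junctions(out / "junctions.bedpe", self.junctions, params=params)
        write_cn_segments(out / "cn.bed", self.cn_profile, params=params)
        write_substitutions(out / "substitutions.vcf", self.substitutions, params=params)
        with open(out / "insertions.tsv", "w") as fh:
            fh.write("junction_id\tindex_in_chain\torigin_chrom\torigin_start"
                     "\torigin_end\tstrand\tlength\n")
            for ins in self.insertions:
                fh.write(
                    f"{ins.dest_junction_id}\t{ins.index_in_chain}\t"
                    f"{ins.origin_chrom or '.'}\t{ins.origin_start or '.'}\t"
                    f"{ins.origin_end or '.'}\t{ins.origin_strand}\t{ins.length}\n"
                )
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=int)


# ---------------------------------------------------------------------------
# shattering
# ---------------------------------------------------------------------------


@dataclass
class DsbEnd:
    eid: int
    frag: int
    side: str            # 'left' or 'right' (of its fragment)
    break_pos: int       # coordinate of the ancestral 3'-strand extent
    orient: str          # R for left-side ends, L for right-side ends
    resection: int
    phase: str           # 'G1' or 'S-G2'
    dsb: int             # index of the originating double-strand break
    fragment_length: int


@dataclass
class ShatterResult:
    fragments: list[tuple[int, int]]
    ends: list[DsbEnd]
    nicks: list[tuple[int, int]]  # (fragment index, position)

    def ends_of(self, frag: int, side: str) -> DsbEnd | None:
        for e in self.ends:
            if e.frag == frag and e.side == side:
                return e
        return None


def _sample_resection(config: SimConfig, rng: np.random.Generator) -> int:
    if rng.random() < config.flush_prob:
        return 0
    r = rng.lognormal(math.log(config.resection_median), config.resection_sigma)
    return int(min(round(r), config.resection_cap))


def simulate_shattering(config: SimConfig, rng: np.random.Generator) -> ShatterResult:
    """Fragment one chromatid with uniformly placed double-strand breaks.

    Each break end is annotated with a sampled resection length and the
    cell-cycle phase in which it will fuse.  Zero breaks leave the
    chromosome intact (empty downstream catalogs).
    """
    n = int(rng.poisson(config.mean_dsbs))
    cuts = (
        np.sort(np.unique(rng.integers(100_000, config.genome_length - 100_000, size=n)))
        if n
        else np.array([], dtype=int)
    )
    if config.min_dsb_spacing > 0 and len(cuts) > 1:
        kept = [int(cuts[0])]
        for c in cuts[1:]:
            if int(c) - kept[-1] >= config.min_dsb_spacing:
                kept.append(int(c))
        cuts = np.array(kept)
    bounds = [0] + [int(c) for c in cuts] + [config.genome_length]
    fragments = [
        (bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)
    ]
    ends: list[DsbEnd] = []
    eid = 0
    for i, p in enumerate(cuts):
        p = int(p)
        flen_left = p - fragments[i][0] + 1
        flen_right = fragments[i + 1][1] - (p + 1) + 1
        for side_frag, side, pos, orient, flen in (
            (i, "right", p, ORIENT_L, flen_left),
            (i + 1, "left", p + 1, ORIENT_R, flen_right),
        ):
            phase = "S-G2" if rng.random() < config.p_brf else "G1"
            ends.append(
                DsbEnd(eid, side_frag, side, pos, orient,
                       _sample_resection(config, rng), phase, i, flen)
            )
            eid += 1
    nicks = []
    for i, (s, e) in enumerate(fragments):
        if e - s > 10_000 and rng.random() < config.nick_prob:
            nicks.append((i, int(rng.integers(s + 2_000, e - 2_000))))
    return ShatterResult(fragments, ends, nicks)


# ---------------------------------------------------------------------------
# the breakage-replication/fusion cycle
# ---------------------------------------------------------------------------


def _blocks_from_g1(
    shatter: ShatterResult, g1_fusions: list[tuple[DsbEnd, DsbEnd]]
) -> list[list[int]]:
    """Group fragments into blocks connected by G1 ligations (order is
    irrelevant for coverage; each block is a list of fragment indices)."""
    parent = list(range(len(shatter.fragments)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in g1_fusions:
        ra, rb = find(a.frag), find(b.frag)
        parent[ra] = rb
    blocks: dict[int, list[int]] = {}
    for f in range(len(shatter.fragments)):
        blocks.setdefault(find(f), []).append(f)
    return [sorted(v) for _, v in sorted(blocks.items())]


def simulate_brf_cycle(
    shatter: ShatterResult, config: SimConfig, rng: np.random.Generator
) -> SimOutput:
    """Run one breakage-replication/fusion cycle over a shattered
    chromatid and emit catalogs plus the truth sidecar."""
    ends = shatter.ends

    # --- G1 ligation (before replication) --------------------------------
    g1_ends = [e for e in ends if e.phase == "G1"]
    order = rng.permutation(len(g1_ends))
    g1_fusions: list[tuple[DsbEnd, DsbEnd]] = []
    g1_bp_pos: dict[int, int] = {}
    for i in range(0, len(order) - 1, 2):
        a, b = g1_ends[order[i]], g1_ends[order[i + 1]]
        g1_fusions.append((a, b))
        for e in (a, b):
            trim = int(rng.integers(0, 11))
            g1_bp_pos[e.eid] = e.break_pos - trim if e.orient == ORIENT_L else e.break_pos + trim
    g1_paired = {e.eid for pair in g1_fusions for e in pair}

    blocks = _blocks_from_g1(shatter, g1_fusions)
    block_of = {f: bi for bi, frags in enumerate(blocks) for f in frags}
    block_len = [
        sum(shatter.fragments[f][1] - shatter.fragments[f][0] + 1 for f in frags)
        for frags in blocks
    ]

    # free ends after G1: S/G2 ends plus leftover (sealed) G1 ends
    fusable = [e for e in ends if e.phase == "S-G2"]

    # --- replication: sister instances of every fusable end --------------
    # Chromatid 'F' inherits the ancestral forward strand: full length at
    # right-side (L) ends, recessed at left-side (R) ends; chromatid 'R'
    # is the mirror image.
    def sister_pos(e: DsbEnd, sister: str) -> tuple[int, str]:
        if e.side == "right":  # orient L, overhang on the forward strand
            return (e.break_pos, "3prime") if sister == "F" else (e.break_pos - e.resection, "5prime")
        return (e.break_pos, "3prime") if sister == "R" else (e.break_pos + e.resection, "5prime")

    # --- S/G2 fusions -----------------------------------------------------
    foldback_ends: list[DsbEnd] = []
    pool: list[tuple[DsbEnd, str]] = []
    for e in fusable:
        if rng.random() < config.p_foldback:
            foldback_ends.append(e)
        else:
            for sister in ("F", "R"):
                if rng.random() >= config.p_unligated:
                    pool.append((e, sister))
    order = rng.permutation(len(pool))
    cross_fusions = [
        (pool[order[i]], pool[order[i + 1]]) for i in range(0, len(order) - 1, 2)
    ]

    # --- molecule assembly ------------------------------------------------
    # nodes: (block, sister); edges: foldbacks and cross fusions
    edges: list[dict] = []
    for e in foldback_ends:
        edges.append({"kind": "foldback", "a": (block_of[e.frag], "F", e), "b": (block_of[e.frag], "R", e)})
    for (ea, sa), (eb, sb) in cross_fusions:
        edges.append({"kind": "cross", "a": (block_of[ea.frag], sa, ea), "b": (block_of[eb.frag], sb, eb)})

    adj: dict[tuple[int, str], list[int]] = {}
    for idx, edge in enumerate(edges):
        for key in ("a", "b"):
            bi, sister, _ = edge[key]
            adj.setdefault((bi, sister), []).append(idx)

    nodes = [(bi, s) for bi in range(len(blocks)) for s in ("F", "R")]
    comp_of: dict[tuple[int, str], int] = {}
    components: list[list[tuple[int, str]]] = []
    for node in nodes:
        if node in comp_of:
            continue
        comp = []
        stack = [node]
        comp_of[node] = len(components)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for idx in adj.get(cur, ()):
                for key in ("a", "b"):
                    bi, sister, _ = edges[idx][key]
                    nxt = (bi, sister)
                    if nxt not in comp_of:
                        comp_of[nxt] = len(components)
                        stack.append(nxt)
        components.append(sorted(comp))

    comp_len = [sum(block_len[bi] for bi, _ in comp) for comp in components]
    retained_comp = {int(np.argmax(comp_len))}
    for ci in range(len(components)):
        if ci not in retained_comp and rng.random() < config.retain_acentric_prob:
            retained_comp.add(ci)
    retained_nodes = {
        node for ci in retained_comp for node in components[ci]
    }
    retained_blocks = {bi for bi, _ in retained_nodes}

    # --- emitted junctions ------------------------------------------------
    chrom = config.chrom
    jspecs: list[dict] = []  # sortable specs, ids assigned afterwards

    def bp_tuple(pos: int, orient: str) -> tuple[int, str]:
        return (max(1, min(pos, config.genome_length)), orient)

    for a, b in g1_fusions:
        if block_of[a.frag] not in retained_blocks:
            continue
        pa, pb = g1_bp_pos[a.eid], g1_bp_pos[b.eid]
        jspecs.append({
            "kind": "g1",
            "bps": [bp_tuple(pa, a.orient) + (a.eid, None), bp_tuple(pb, b.orient) + (b.eid, None)],
            "hom": int(rng.integers(0, 3)),
            "phase": "G1",
        })
    for edge in edges:
        ci = comp_of[edge["a"][0], edge["a"][1]]
        if ci not in retained_comp:
            continue
        bps = []
        for key in ("a", "b"):
            _, sister, e = edge[key]
            pos, polarity = sister_pos(e, sister)
            bps.append(bp_tuple(pos, e.orient) + (e.eid, polarity))
        jspecs.append({
            "kind": edge["kind"],
            "bps": bps,
            "hom": int(rng.integers(0, 7)),
            "phase": "S-G2",
        })
    for frag_i, pos in shatter.nicks:
        if block_of[frag_i] not in retained_blocks:
            continue
        if rng.random() < 0.5:  # replication bypass: small over-replicated overlap
            ov = int(rng.integers(20, 400))
            bps = [bp_tuple(pos, ORIENT_R) + (None, None), bp_tuple(pos + ov, ORIENT_L) + (None, None)]
            kind = "ssb_overlap"
        else:                    # simple fusion of the replicated gap ends
            gap = int(rng.integers(1, 50))
            bps = [bp_tuple(pos, ORIENT_L) + (None, None), bp_tuple(pos + gap, ORIENT_R) + (None, None)]
            kind = "ssb_gapped"
        jspecs.append({"kind": kind, "bps": bps, "hom": int(rng.integers(0, 3)), "phase": "S-G2"})

    jspecs.sort(key=lambda s: (min(b[0] for b in s["bps"]), max(b[0] for b in s["bps"]), s["kind"]))

    # --- insertions at S/G2 junctions ------------------------------------
    sg2_spec_idx = [i for i, s in enumerate(jspecs) if s["kind"] in ("foldback", "cross")]
    pool_frags: list[dict] = []
    emitted_end_ids = {
        b[2] for s in jspecs for b in s["bps"] if b[2] is not None
    }
    donors = sorted(
        (e for e in fusable
         if e.resection >= config.min_donor_overhang and e.eid in emitted_end_ids),
        key=lambda e: -e.resection,
    )[: config.max_tile_donors]
    for e in donors:
        lo = min(e.break_pos, e.break_pos + (e.resection if e.side == "left" else -e.resection))
        hi = max(e.break_pos, e.break_pos + (e.resection if e.side == "left" else -e.resection))
        # tiling proceeds across the overhang with small gaps/overlaps
        cur = lo
        while cur < hi - 30:
            length = max(20, int(round(rng.lognormal(
                math.log(config.insertion_median), config.insertion_sigma))))
            end = cur + length - 1
            if end > hi:
                break
            pool_frags.append({
                "origin": (cur, end),
                "tile": e.eid,
                # displaced ssDNA is the strand complementary to the overhang
                "native_strand": "fwd" if e.side == "left" else "rev",
            })
            gap = int(round(rng.normal(config.tile_gap_mean, config.tile_gap_sd)))
            cur = end + 1 + max(gap, -9)  # overlaps capped below 10 bp
    for _ in range(int(rng.poisson(config.distal_insertions_mean))):
        length = max(20, int(round(rng.lognormal(
            math.log(config.insertion_median), config.insertion_sigma))))
        start = int(rng.integers(1, config.genome_length - length))
        pool_frags.append({"origin": (start, start + length - 1), "tile": None,
                           "native_strand": "fwd" if rng.random() < 0.5 else "rev"})

    assignments: dict[int, list[dict]] = {i: [] for i in sg2_spec_idx}
    if sg2_spec_idx and pool_frags:
        order = rng.permutation(len(pool_frags))
        frag_iter = [pool_frags[i] for i in order]
        junction_order = list(rng.permutation(sg2_spec_idx))
        pos = 0
        turn = 0
        while pos < len(frag_iter):
            target = junction_order[turn % len(junction_order)]
            take = 1 + int(rng.poisson(config.chain_len_mean))
            for frag in frag_iter[pos : pos + take]:
                assignments[target].append(frag)
            pos += take
            turn += 1

    # --- build Junction objects and the truth sidecar ---------------------
    junctions: list[Junction] = []
    truth_bps: list[dict] = []
    truth_insertions: list[dict] = []
    for i, spec in enumerate(jspecs):
        jid = f"J{i + 1:04d}"
        fragments = []
        for idx, frag in enumerate(assignments.get(i, ()), start=1):
            start, end = frag["origin"]
            if rng.random() < config.strand_known_prob:
                strand = "fwd" if rng.random() < 0.5 else "rev"
            else:
                strand = "unknown"
            fragments.append(Insertion(
                dest_junction_id=jid,
                index_in_chain=idx,
                origin_chrom=chrom,
                origin_start=int(start),
                origin_end=int(end),
                origin_strand=strand,
                length=int(end - start + 1),
                sub_junction_homology=int(rng.integers(0, 7)),
            ))
            truth_insertions.append({
                "junction_id": jid, "index": idx, "origin_start": int(start),
                "origin_end": int(end), "strand": strand, "tile_id": frag["tile"],
                "native_strand": frag["native_strand"],
            })
        (p1, o1, e1, pol1), (p2, o2, e2, pol2) = spec["bps"]
        j = make_junction(
            jid,
            Breakpoint(chrom, p1, o1, SAMPLE_ID, jid),
            Breakpoint(chrom, p2, o2, SAMPLE_ID, jid),
            fragments,
            spec["hom"],
        )
        junctions.append(j)
        # truth rows follow the junction's normalized breakpoint order
        for bp, (pos0, _, eid, pol) in zip(
            j.breakpoints,
            sorted(spec["bps"], key=lambda b: b[0]) if spec["bps"][0][0] != spec["bps"][1][0]
            else spec["bps"],
        ):
            truth_bps.append({
                "junction_id": jid, "chrom": chrom, "pos": bp.pos,
                "orient": bp.orient, "end_id": eid, "polarity": pol,
                "phase": spec["phase"], "kind": spec["kind"],
            })

    # sister pairs: both sister breakpoints of one ancestral end emitted
    emitted_by_end: dict[int, dict[str, int]] = {}
    for row in truth_bps:
        if row["end_id"] is not None and row["polarity"] is not None:
            emitted_by_end.setdefault(row["end_id"], {})[row["polarity"]] = row["pos"]
    end_by_id = {e.eid: e for e in ends}
    sister_pairs = []
    for eid, poles in sorted(emitted_by_end.items()):
        if "3prime" in poles and "5prime" in poles:
            e = end_by_id[eid]
            sister_pairs.append({
                "end_id": eid,
                "chrom": chrom,
                "orient": e.orient,
                "pos_a": min(poles.values()),
                "pos_b": max(poles.values()),
                "offset": e.resection,
                "side": e.side,
                "fragment_length": e.fragment_length,
            })

    # G1 gapped pairs: both ends of one DSB ligated in G1 and retained
    g1_by_dsb: dict[int, list[int]] = {}
    for row in truth_bps:
        if row["phase"] == "G1" and row["end_id"] is not None:
            e = end_by_id[row["end_id"]]
            g1_by_dsb.setdefault(e.dsb, []).append(row["pos"])
    g1_gapped_pairs = [
        {"dsb": d, "pos_a": min(v), "pos_b": max(v)}
        for d, v in sorted(g1_by_dsb.items()) if len(v) == 2
    ]

    # --- retained segments and copy number --------------------------------
    retained_segments: list[dict] = []
    for bi, sister in sorted(retained_nodes):
        for f in blocks[bi]:
            s, e_pos = shatter.fragments[f]
            lo, hi = s, e_pos
            for side, port_pos in (("left", s), ("right", e_pos)):
                end = shatter.ends_of(f, side)
                if end is None:
                    continue
                if end.phase == "G1" and end.eid in g1_paired:
                    # NHEJ trimming is shared by both sisters
                    if side == "left":
                        lo = max(lo, g1_bp_pos[end.eid])
                    else:
                        hi = min(hi, g1_bp_pos[end.eid])
                elif end.phase == "S-G2":
                    pos, _ = sister_pos(end, sister)
                    if side == "left":
                        lo = max(lo, pos)
                    else:
                        hi = min(hi, pos)
            if lo <= hi:
                retained_segments.append({
                    "block": bi, "sister": sister, "fragment": f,
                    "start": int(lo), "end": int(hi),
                })

    cn_profile = _coverage_profile(config, retained_segments)

    # --- deamination in retained overhang offsets --------------------------
    substitutions: list[Substitution] = []
    truth_subs: list[dict] = []
    overhang_truth: list[dict] = []
    bases = "ACGT"
    for pair in sister_pairs:
        if pair["offset"] < 50:
            continue
        lo, hi = pair["pos_a"], pair["pos_b"]
        side = "left" if pair["orient"] == ORIENT_R else "right"
        expected = "rev_C" if side == "left" else "fwd_C"
        overhang_truth.append({**pair, "offset_side": side, "expected_class": expected})
        if rng.random() >= config.deamination_prob:
            continue
        n_subs = 3 + int(rng.poisson(config.deamination_extra))
        window = min(hi - lo, 1_500)
        w_start = lo + int(rng.integers(0, hi - lo - window + 1)) if hi - lo > window else lo
        positions = np.sort(rng.choice(
            np.arange(w_start, w_start + window + 1), size=min(n_subs, window), replace=False))
        for pos in positions:
            if expected == "fwd_C":
                ref, alt = "C", rng.choice(["T", "T", "T", "G", "A"])
                ctx = "T" + ref + bases[rng.integers(0, 4)]
            else:
                ref, alt = "G", rng.choice(["A", "A", "A", "C", "T"])
                ctx = bases[rng.integers(0, 4)] + ref + "A"
            substitutions.append(Substitution(chrom, int(pos), ref, str(alt), ctx))
            truth_subs.append({"pos": int(pos), "end_id": pair["end_id"],
                               "class": expected, "in_offset": True})
    for _ in range(int(rng.poisson(config.background_substitutions))):
        pos = int(rng.integers(1, config.genome_length))
        ref = bases[rng.integers(0, 4)]
        alt = rng.choice([b for b in bases if b != ref])
        ctx = bases[rng.integers(0, 4)] + ref + bases[rng.integers(0, 4)]
        substitutions.append(Substitution(chrom, pos, ref, str(alt), ctx))
    substitutions.sort(key=lambda s: (s.chrom, s.pos))

    # truth tiles: only emitted members count
    tile_members: dict[int, list[dict]] = {}
    for row in truth_insertions:
        if row["tile_id"] is not None:
            tile_members.setdefault(row["tile_id"], []).append(row)
    truth_tiles = [
        {"tile_id": tid, "n_members": len(members),
         "start": min(m["origin_start"] for m in members),
         "end": max(m["origin_end"] for m in members)}
        for tid, members in sorted(tile_members.items())
        if len(members) >= 4
    ]
    truth_chains = [
        {"junction_id": jid, "n_insertions": len(rows)}
        for jid, rows in sorted(
            _group_by(truth_insertions, "junction_id").items())
        if len(rows) >= 2
    ]

    truth = {
        "mode": config.mode,
        "seed": config.seed,
        "chrom": chrom,
        "genome_length": config.genome_length,
        "n_dsbs": len({e.dsb for e in ends}),
        "breakpoints": truth_bps,
        "sister_pairs": sister_pairs,
        "g1_gapped_pairs": g1_gapped_pairs,
        "retained_segments": retained_segments,
        "insertions": truth_insertions,
        "tiles": truth_tiles,
        "chains": truth_chains,
        "substitutions": truth_subs,
        "overhang_intervals": overhang_truth,
        "foldback_junction_ids": [
            f"J{i + 1:04d}" for i, s in enumerate(jspecs) if s["kind"] == "foldback"
        ],
    }
    return SimOutput(config, junctions, cn_profile, substitutions, truth)


def _group_by(rows: list[dict], key: str) -> dict:
    out: dict = {}
    for row in rows:
        out.setdefault(row[key], []).append(row)
    return out


def _coverage_profile(config: SimConfig, segments: Sequence[dict]) -> CopyNumberProfile:
    """Haplotype A: coverage of the retained rearranged segments (explicit
    zero segments included); haplotype B: the intact homolog."""
    events: dict[int, int] = {}
    for seg in segments:
        events[seg["start"]] = events.get(seg["start"], 0) + 1
        events[seg["end"] + 1] = events.get(seg["end"] + 1, 0) - 1
    points = sorted(set([1, config.genome_length + 1]) | set(events))
    out = []
    depth = 0
    for p, nxt in zip(points, points[1:]):
        depth += events.get(p, 0)
        if 1 <= p <= config.genome_length:
            end = min(nxt - 1, config.genome_length)
            if end >= p:
                out.append(CopyNumberSegment(config.chrom, p, end, depth, "A"))
    out.append(CopyNumberSegment(config.chrom, 1, config.genome_length, 1, "B"))
    return CopyNumberProfile(out)


# ---------------------------------------------------------------------------
# MMBIR mode
# ---------------------------------------------------------------------------


def simulate_mmbir(config: SimConfig, rng: np.random.Generator) -> SimOutput:
    """Iterative template-switching insertions (microhomology-mediated
    break-induced replication).

    Conservative synthesis adds every insertion of a chain to the same
    nascent strand; template switches jump tens of kb to Mb away (so
    origins do not tile), except for occasional short backward re-invasions
    that re-copy >= 10 bp of the previous template (partial origin
    overlap).  Overlap jumps are never consecutive, so origin clusters
    never reach tiling size.
    """
    chrom = config.chrom
    G = config.genome_length
    junctions = []
    truth_insertions = []
    placed: list[int] = []  # origin starts; fresh invasions avoid reusing loci

    scatter = 20_000  # fresh invasions land clear of previously used loci

    def fresh(pos: int, length: int) -> bool:
        return all(abs(pos - p) > scatter for p in placed)

    def draw_start(anchor: int, length: int) -> int:
        for _ in range(50):
            jump = int(round(10 ** rng.uniform(4.3, 6.3)))
            sign = 1 if rng.random() < 0.5 else -1
            start = min(max(1, anchor + sign * jump), G - length)
            if fresh(start, length):
                return start
        return start

    for c in range(config.mmbir_chains):
        jid = f"M{c + 1:04d}"
        n_ins = 2 + int(rng.poisson(2.0))
        strand = "fwd" if rng.random() < 0.5 else "rev"
        start = int(rng.integers(2_000_000, G - 2_000_000))
        fragments = []
        prev: tuple[int, int] | None = None
        last_overlap = False
        for idx in range(1, n_ins + 1):
            length = max(50, int(round(rng.normal(config.mmbir_synthesis_mean, 150.0))))
            if prev is not None:
                if not last_overlap and rng.random() < config.mmbir_overlap_prob:
                    ov = int(rng.integers(10, min(150, prev[1] - prev[0])))
                    start = prev[1] - ov + 1
                    last_overlap = True
                else:
                    start = draw_start(prev[0], length)
                    last_overlap = False
            elif not fresh(start, length):
                start = draw_start(start, length)
            origin = (start, start + length - 1)
            placed.append(start)
            fragments.append(Insertion(
                dest_junction_id=jid, index_in_chain=idx,
                origin_chrom=chrom, origin_start=origin[0], origin_end=origin[1],
                origin_strand=strand, length=length,
                sub_junction_homology=int(rng.integers(2, 9)),
            ))
            truth_insertions.append({
                "junction_id": jid, "index": idx, "origin_start": origin[0],
                "origin_end": origin[1], "strand": strand, "tile_id": None,
            })
            prev = origin
        anchor = int(rng.integers(1_000_000, G - 1_000_000))
        partner = int(rng.integers(1_000_000, G - 1_000_000))
        junctions.append(make_junction(
            jid,
            Breakpoint(chrom, anchor, ORIENT_L, SAMPLE_ID, jid),
            Breakpoint(chrom, partner, ORIENT_R, SAMPLE_ID, jid),
            fragments,
            int(rng.integers(2, 9)),
        ))
    profile = CopyNumberProfile([CopyNumberSegment(chrom, 1, G, 1, "B")])
    truth = {
        "mode": MODE_MMBIR,
        "seed": config.seed,
        "chrom": chrom,
        "insertions": truth_insertions,
        "tiles": [],
        "chains": [
            {"junction_id": jid, "n_insertions": len(rows)}
            for jid, rows in sorted(_group_by(truth_insertions, "junction_id").items())
            if len(rows) >= 2
        ],
        "sister_pairs": [],
        "retained_segments": [],
    }
    return SimOutput(config, junctions, profile, [], truth)


# ---------------------------------------------------------------------------
# amplification modes
# ---------------------------------------------------------------------------


def _segregate(copies: int, generations: int, rng: np.random.Generator, cap: int) -> int:
    c = copies
    for _ in range(generations):
        c = max(1, int(rng.binomial(2 * c, 0.5)))
        if c > cap:
            return cap
    return c


def simulate_amplification(
    config: SimConfig,
    mode: str | None = None,
    generations: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimOutput:
    """Amplify a single acentric fragment.

    ``episome_I``: head-to-tail circularization (one junction), copy
    number amplified by uneven segregation.  ``episome_II``: sister-end
    fusion on both sides makes a dimeric circle bounded by two foldbacks
    of opposite orientation.  ``linear_inverted``: sister-end fusion on
    one side per generation doubles a linear inverted array — after g
    generations the amplicon is at 2^g copies and every junction is a
    foldback confined within the amplicon, clustered at the edges within
    the resection scale.
    """
    mode = mode or config.amplification_mode
    g = config.generations if generations is None else generations
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if g < 1:
        raise ValueError("generations must be >= 1")
    chrom, s, e = config.chrom, config.fragment_start, config.fragment_end
    junctions: list[Junction] = []
    truth: dict = {"mode": mode, "generations": g, "fragment": [s, e], "seed": config.seed}
    segs: list[CopyNumberSegment]

    if mode == AMP_EPISOME_I:
        n = _segregate(1, g, rng, config.copy_cap)
        junctions.append(make_junction(
            "A0001",
            Breakpoint(chrom, s, ORIENT_R, SAMPLE_ID, "A0001"),
            Breakpoint(chrom, e, ORIENT_L, SAMPLE_ID, "A0001"),
        ))
        segs = [CopyNumberSegment(chrom, s, e, n, "A")]
        truth["amplicon_copy"] = n
    elif mode == AMP_EPISOME_II:
        r1 = max(1, _sample_resection(config, rng))
        r2 = max(1, _sample_resection(config, rng))
        junctions.append(make_junction(
            "A0001",
            Breakpoint(chrom, s, ORIENT_R, SAMPLE_ID, "A0001"),
            Breakpoint(chrom, s + r1, ORIENT_R, SAMPLE_ID, "A0001"),
        ))
        junctions.append(make_junction(
            "A0002",
            Breakpoint(chrom, e - r2, ORIENT_L, SAMPLE_ID, "A0002"),
            Breakpoint(chrom, e, ORIENT_L, SAMPLE_ID, "A0002"),
        ))
        n = _segregate(1, g, rng, config.copy_cap)  # dimeric circles
        segs = [
            CopyNumberSegment(chrom, s, s + r1 - 1, n, "A"),
            CopyNumberSegment(chrom, s + r1, e - r2, 2 * n, "A"),
            CopyNumberSegment(chrom, e - r2 + 1, e, n, "A"),
        ]
        truth["amplicon_copy"] = 2 * n
    elif mode == AMP_LINEAR_INVERTED:
        if 2 ** g > config.copy_cap:
            g = int(math.log2(config.copy_cap))
            log.warning("generations truncated to %d by the copy cap", g)
            truth["generations"] = g
        ivs: list[list[int]] = [[s, e]]
        jid = 0
        for gen in range(g):
            r = max(1, _sample_resection(config, rng))
            jid += 1
            name = f"A{jid:04d}"
            if gen == 0:  # tail-to-tail fusion at the right edge
                junctions.append(make_junction(
                    name,
                    Breakpoint(chrom, e - r, ORIENT_L, SAMPLE_ID, name),
                    Breakpoint(chrom, e, ORIENT_L, SAMPLE_ID, name),
                ))
                trimmed = [list(iv) for iv in ivs]
                trimmed[-1][1] -= r
                ivs = ivs + trimmed[::-1]
            else:         # head-to-head fusions cluster at the left edge
                junctions.append(make_junction(
                    name,
                    Breakpoint(chrom, s, ORIENT_R, SAMPLE_ID, name),
                    Breakpoint(chrom, s + r, ORIENT_R, SAMPLE_ID, name),
                ))
                trimmed = [list(iv) for iv in ivs]
                trimmed[0][0] += r
                ivs = trimmed[::-1] + ivs
        events: dict[int, int] = {}
        for lo, hi in ivs:
            events[lo] = events.get(lo, 0) + 1
            events[hi + 1] = events.get(hi + 1, 0) - 1
        points = sorted(events)
        depth = 0
        segs = []
        for p, nxt in zip(points, points[1:]):
            depth += events.get(p, 0)
            if depth > 0 and nxt - 1 >= p:
                segs.append(CopyNumberSegment(chrom, p, nxt - 1, depth, "A"))
        truth["amplicon_copy"] = 2 ** g
    else:
        raise ValueError(f"unknown amplification mode {mode!r}")

    segs.append(CopyNumberSegment(chrom, 1, config.genome_length, 1, "B"))
    truth["junction_ids"] = [j.id for j in junctions]
    truth["sister_pairs"] = []
    truth["retained_segments"] = []
    return SimOutput(config, junctions, CopyNumberProfile(segs), [], truth)


# ---------------------------------------------------------------------------
# entry point
# ---------------------------------------------------------------------------


def simulate(config: SimConfig) -> SimOutput:
    """Run the simulator described by ``config`` (deterministic for a
    given config and seed)."""
    rng = np.random.default_rng(config.seed)
    if config.amplification_mode != AMP_NONE:
        return simulate_amplification(config, rng=rng)
    if config.mode == MODE_MMBIR:
        return simulate_mmbir(config, rng)
    if config.mode not in (MODE_BRF, MODE_MIXED):
        raise ValueError(f"unknown simulation mode {config.mode!r}")
    shatter = simulate_shattering(config, rng)
    return simulate_brf_cycle(shatter, config, rng)
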