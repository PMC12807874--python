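"""Short-insertion extraction, origin tiling, chains and the
strand-concordance test.

Short inserted fragments at rearrangement junctions carry three signals
about their mechanism of origin:

* *origin tiling* — insertions mapping back to one locus that line up one
  after another with little gap or overlap indicate discontinuous
  gap-filling synthesis across a single-stranded overhang, not random
  template switching;
* *chains* — two or more tandem insertions at one junction;
* *strand concordance* — a conservative replicative process (MMBIR) adds
  every insertion of a chain to the same nascent strand, so any pair of
  consecutive insertions on opposite strands excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .adjacency import CLASS_INSERTION_OVERLAP, AdjacencyCatalog
from .core_model import ORIENT_L, ORIENT_R, Breakpoint, Insertion, Junction

DEFAULT_MAX_SPAN = 10_000     # subclone-resolved analysis; catalog scans share
                              # the 20 kb adjacency threshold instead
DEFAULT_TILE_WINDOW = 10_000
DEFAULT_MIN_MEMBERS = 4
DEFAULT_NEAR_WINDOW = 10_000
SMALL_GAP_BP = 50             # |gap| below this counts as "little gap or overlap"
OVERLAP_BP = 10               # origin overlap at least this large is "material"

VERDICT_INCOMPATIBLE = "MMBIR_incompatible"
VERDICT_COMPATIBLE = "MMBIR_compatible"
VERDICT_INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Tile:
    """Four or more insertions originating from adjacent locations.

    ``gaps[i]`` is the signed distance between coordinate-sorted members i
    and i+1: positive = unsampled bases between origins, negative = origin
    overlap of that many bases, zero = flush.
    """

    members: tuple[Insertion, ...]
    gaps: tuple[int, ...]
    chrom: str
    start: int
    end: int
    adjacent_breakpoint: tuple[Breakpoint, str] | None = None  # (bp, side)
    inferred_strand: str | None = None

    @property
    def frac_small_gap(self) -> float:
        return sum(abs(g) <= SMALL_GAP_BP for g in self.gaps) / len(self.gaps)

    @property
    def frac_overlap(self) -> float:
        return sum(g <= -OVERLAP_BP for g in self.gaps) / len(self.gaps)


@dataclass(frozen=True)
class Chain:
    junction_id: str
    insertions: tuple[Insertion, ...]
    same_strand_pairs: int
    opposite_strand_pairs: int

    @property
    def strand_pattern(self) -> str:
        return "".join(
            {"fwd": ">", "rev": "<", "unknown": "?"}[i.origin_strand]
            for i in self.insertions
        )

    @property
    def informative_pairs(self) -> int:
        return self.same_strand_pairs + self.opposite_strand_pairs


def extract_insertions(
    junctions: Sequence[Junction],
    catalog: AdjacencyCatalog | None = None,
    max_span: int = DEFAULT_MAX_SPAN,
    near_window: int = DEFAULT_NEAR_WINDOW,
) -> list[Insertion]:
    """Collect short insertions from junction annotations and, when an
    adjacency catalog is given, from insertion/overlap breakpoint pairs.

    Junctions carrying explicit inserted fragments contribute one record
    per fragment.  Catalog-level (R, L) adjacency pairs spanning at most
    ``max_span`` are emitted as candidate insertion/overlap records (no
    distinction is made between the two) with the enclosed interval as the
    origin.  Each mapped insertion is annotated with the distance to the
    nearest other breakpoint within ``near_window``.
    """
    out: list[Insertion] = []
    for j in junctions:
        out.extend(j.inserted_fragments)
    if catalog is not None:
        for pair in catalog.pairs_of(CLASS_INSERTION_OVERLAP):
            a, b = pair.bp_a, pair.bp_b
            if pair.distance > max_span:
                continue
            out.append(
                Insertion(
                    dest_junction_id=f"{a.junction_id}|{b.junction_id}",
                    index_in_chain=1,
                    origin_chrom=a.chrom,
                    origin_start=a.pos,
                    origin_end=b.pos,
                    origin_strand="unknown",
                    length=b.pos - a.pos + 1,
                )
            )
    all_bps = [bp for j in junctions for bp in j.breakpoints]
    annotated = []
    for ins in out:
        if not ins.has_origin:
            annotated.append(ins)
            continue
        best: tuple[int, str] | None = None
        for bp in all_bps:
            if bp.chrom != ins.origin_chrom or bp.junction_id == ins.dest_junction_id:
                continue
            if ins.origin_start <= bp.pos <= ins.origin_end:
                d = 0
            else:
                d = min(abs(bp.pos - ins.origin_start), abs(bp.pos - ins.origin_end))
            if d <= near_window and (best is None or d < best[0]):
                best = (d, bp.junction_id)
        annotated.append(replace(ins, nearest_ancestral_bp=best))
    return annotated


def detect_tiles(
    insertions: Iterable[Insertion],
    tile_window: int = DEFAULT_TILE_WINDOW,
    min_members: int = DEFAULT_MIN_MEMBERS,
    breakpoints: Sequence[Breakpoint] | None = None,
    flank_window: int = DEFAULT_NEAR_WINDOW,
) -> list[Tile]:
    """Single-linkage clustering of insertion origins into tiles.

    Origins whose intervals are within ``tile_window`` of each other (gap
    between intervals, not start-to-start) join one cluster; clusters with
    at least ``min_members`` are reported.  Gap/overlap distances are
    computed between coordinate-sorted members, not destination order.
    When breakpoints are supplied the nearest one within ``flank_window``
    of the tile extent is recorded with its side, and — if it is the inner
    member of a parallel pair — the origin strand implied by the
    3'-overhang rule is recorded as inferred (explicit per-insertion
    strands are never overwritten).
    """
    mapped = sorted(
        (i for i in insertions if i.has_origin),
        key=lambda i: (i.origin_chrom, i.origin_start, i.origin_end),
    )
    tiles: list[Tile] = []
    cluster: list[Insertion] = []

    def flush_cluster() -> None:
        if len(cluster) < min_members:
            return
        gaps = tuple(
            b.origin_start - a.origin_end - 1 for a, b in zip(cluster, cluster[1:])
        )
        chrom = cluster[0].origin_chrom
        start, end = cluster[0].origin_start, max(i.origin_end for i in cluster)
        adjacent = None
        inferred = None
        if breakpoints:
            best = None
            for bp in breakpoints:
                if bp.chrom != chrom:
                    continue
                if start <= bp.pos <= end:
                    d, side = 0, "inside"
                elif bp.pos < start:
                    d, side = start - bp.pos, "left"
                else:
                    d, side = bp.pos - end, "right"
                if d <= flank_window and (best is None or d < best[0]):
                    best = (d, bp, side)
            if best is not None:
                _, bp, side = best
                adjacent = (bp, side)
                # 3'-overhang rule: a tile abutting the 5'-derived (inner)
                # breakpoint of an R/R pair copies the reverse-strand
                # overhang, so the displaced ssDNA is forward strand.
                if bp.orient == ORIENT_R:
                    inferred = "fwd"
                elif bp.orient == ORIENT_L:
                    inferred = "rev"
        tiles.append(Tile(tuple(cluster), gaps, chrom, start, end, adjacent, inferred))

    prev_chrom, prev_end = None, None
    for ins in mapped:
        if (
            cluster
            and ins.origin_chrom == prev_chrom
            and ins.origin_start - prev_end - 1 <= tile_window
        ):
            cluster.append(ins)
            prev_end = max(prev_end, ins.origin_end)
        else:
            flush_cluster()
            cluster = [ins]
            prev_chrom, prev_end = ins.origin_chrom, ins.origin_end
    flush_cluster()
    return tiles


def assemble_chains(junctions: Iterable[Junction]) -> list[Chain]:
    """One chain per junction carrying two or more insertions, in junction
    order.  Consecutive pairs with both strands known are tallied as same-
    or opposite-strand."""
    chains = []
    for j in junctions:
        ins = j.inserted_fragments
        if len(ins) < 2:
            continue
        same = opp = 0
        for a, b in zip(ins, ins[1:]):
            if a.origin_strand == "unknown" or b.origin_strand == "unknown":
                continue
            if a.origin_strand == b.origin_strand:
                same += 1
            else:
                opp += 1
        chains.append(Chain(j.id, ins, same, opp))
    return chains


def strand_concordance(chains: Sequence[Chain]) -> dict:
    """Totals of same/opposite-strand consecutive insertion pairs across
    chains, and the resulting verdict on a conservative-synthesis (MMBIR)
    origin: any opposite-strand pair is incompatible with it."""
    same = sum(c.same_strand_pairs for c in chains)
    opp = sum(c.opposite_strand_pairs for c in chains)
    if same + opp == 0:
        verdict = VERDICT_INDETERMINATE
    elif opp > 0:
        verdict = VERDICT_INCOMPATIBLE
    else:
        verdict = VERDICT_COMPATIBLE
    per_chain = [
        {
            "junction_id": c.junction_id,
            "pattern": c.strand_pattern,
            "same": c.same_strand_pairs,
            "opposite": c.opposite_strand_pairs,
            "violates_strand_coordination": c.opposite_strand_pairs > 0,
        }
        for c in chains
    ]
    return {
        "same": same,
        "opposite": opp,
        "verdict": verdict,
        "chains": per_chain,
    }
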