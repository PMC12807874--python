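"""Reconstruction of duplicated (rearranged) segments from subclonal
copy-number profiles and junction catalogs.

Implements four rules for determining segment boundaries and sister
phasing, and labels what they cannot resolve rather than attempting a
full karyotype assembly:

1. per-breakpoint copy change from the segmental copy-number difference
   across the breakpoint, with a partner-breakpoint fallback when two
   breakpoints share one bin;
2. retained regions flanked by deletions directly determine segment
   boundaries;
3. a segment determined in one subclone is shared with any other subclone
   in which both boundary breakpoints recur (assumes no non-allelic
   homologous recombination between duplicated copies);
4. a multi-copy region flanked by parallel pairs on both sides must
   consist of two sister segments phased outer-left-with-inner-right:
   replication of one resected ancestral fragment yields one sister
   bounded by the two 3'-derived (outer-left, inner-right... see
   :func:`phase_sisters`) ends and one bounded by the two 5'-derived ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .adjacency import CLASS_PARALLEL, AdjacencyPair
from .core_model import (
    ORIENT_L,
    ORIENT_R,
    Breakpoint,
    CopyNumberProfile,
    Junction,
)

DEFAULT_BIN = 25_000

P5 = "5prime"
P3 = "3prime"
UNKNOWN = "unknown"


@dataclass
class RearrangedSegment:
    chrom: str
    start: int               # left boundary (R breakpoint position)
    end: int                 # right boundary (L breakpoint position)
    left_bp: Breakpoint | None = None
    right_bp: Breakpoint | None = None
    copies: dict[str, int] = field(default_factory=dict)  # subclone -> copy
    sister_partner: int | None = None                     # index into result list
    end_provenance: dict[str, str] = field(
        default_factory=lambda: {"left": UNKNOWN, "right": UNKNOWN}
    )
    confirmed: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BreakpointCopyChange:
    breakpoint: Breakpoint
    change: float | None     # copy(right bin) - copy(left bin); None in a gap
    substituted: bool = False  # True when taken from the partner breakpoint
    copy_neutral: bool = False


def breakpoint_copy_numbers(
    profile: CopyNumberProfile,
    breakpoints: Sequence[Breakpoint],
    junctions: Sequence[Junction] | None = None,
    bin_size: int = DEFAULT_BIN,
    haplotype: str | None = "sum",
) -> list[BreakpointCopyChange]:
    """Copy change across each breakpoint at ``bin_size`` resolution.

    When another breakpoint lies within one bin (ambiguous transition),
    the partner breakpoint's unambiguous change magnitude is substituted,
    signed by the breakpoint's own orientation, and the record flagged.
    """
    half = bin_size // 2
    positions = sorted(bp.pos for bp in breakpoints)
    jmap = {j.id: j for j in junctions} if junctions else {}

    def raw_change(bp: Breakpoint) -> tuple[float | None, bool]:
        left = profile.copy_at(bp.chrom, bp.pos - half, haplotype)
        right = profile.copy_at(bp.chrom, bp.pos + half, haplotype)
        if left is None or right is None:
            return None, False
        return right - left, True

    def ambiguous(bp: Breakpoint) -> bool:
        # another breakpoint within one bin blurs the transition
        return any(0 < abs(p - bp.pos) <= bin_size for p in positions)

    out = []
    for bp in breakpoints:
        change, in_profile = raw_change(bp)
        if not in_profile:
            out.append(BreakpointCopyChange(bp, None))
            continue
        if ambiguous(bp) and bp.junction_id in jmap:
            j = jmap[bp.junction_id]
            partner = j.bp2 if (j.bp1.chrom, j.bp1.pos) == (bp.chrom, bp.pos) else j.bp1
            if not ambiguous(partner):
                p_change, ok = raw_change(partner)
                if ok and p_change is not None:
                    signed = abs(p_change) if bp.orient == ORIENT_R else -abs(p_change)
                    out.append(BreakpointCopyChange(bp, signed, substituted=True))
                    continue
        out.append(BreakpointCopyChange(bp, change, copy_neutral=change == 0))
    return out


def segments_from_deletion_flanks(
    profiles: Mapping[str, CopyNumberProfile],
    junctions: Mapping[str, Sequence[Junction]],
    source_subclone: str,
    haplotype: str | None = None,
    tol: int = 5,
) -> list[RearrangedSegment]:
    """Determine segments in a subclone with interspersed deletions, then
    propagate them to subclones where both boundary breakpoints recur.

    In the source subclone's haplotype profile, maximal retained runs
    (copy > 0) flanked by zero-copy segments on both sides become
    RearrangedSegments; a boundary is *confirmed* when a junction
    breakpoint matches it within ``tol``.  A segment is shared with
    another subclone when both boundaries match junction breakpoints
    there, and its copy there is read from that subclone's profile.
    """
    profile = profiles[source_subclone]
    segments: list[RearrangedSegment] = []

    def junction_bp_match(subclone: str, chrom: str, pos: int, orient: str) -> Breakpoint | None:
        for j in junctions.get(subclone, ()):
            for bp in j.breakpoints:
                if bp.chrom == chrom and bp.orient == orient and abs(bp.pos - pos) <= tol:
                    return bp
        return None

    for (chrom, hap), segs in profile.segments.items():
        if hap != haplotype:
            continue
        for i, seg in enumerate(segs):
            if seg.copy <= 0:
                continue
            left_del = i > 0 and segs[i - 1].copy == 0 and segs[i - 1].end + 1 == seg.start
            right_del = (
                i + 1 < len(segs)
                and segs[i + 1].copy == 0
                and seg.end + 1 == segs[i + 1].start
            )
            if not (left_del and right_del):
                continue
            lbp = junction_bp_match(source_subclone, chrom, seg.start, ORIENT_R)
            rbp = junction_bp_match(source_subclone, chrom, seg.end, ORIENT_L)
            rec = RearrangedSegment(
                chrom,
                seg.start,
                seg.end,
                left_bp=lbp,
                right_bp=rbp,
                copies={source_subclone: int(seg.copy)},
                confirmed=lbp is not None and rbp is not None,
            )
            for other, prof in profiles.items():
                if other == source_subclone:
                    continue
                if (
                    junction_bp_match(other, chrom, seg.start, ORIENT_R) is not None
                    and junction_bp_match(other, chrom, seg.end, ORIENT_L) is not None
                ):
                    mid = (seg.start + seg.end) // 2
                    copy = prof.copy_at(chrom, mid, haplotype)
                    rec.copies[other] = int(copy) if copy is not None else 0
            segments.append(rec)
    return segments


def phase_sisters(
    left_pair: AdjacencyPair,
    right_pair: AdjacencyPair,
) -> tuple[RearrangedSegment, RearrangedSegment]:
    """Phase a multi-copy region flanked by parallel pairs into two sister
    segments.

    With the left R/R pair at a1 < a2 and the right L/L pair at
    b1 < b2, 5'-resection geometry forces sisters [a1, b1] and [a2, b2]:
    each sister pairs one 3'-derived end with one 5'-derived end, never
    the two outer ends together (which would exceed the ancestral
    fragment).  End provenance: a1 -> 3', a2 -> 5', b1 -> 5', b2 -> 3'.
    A flush pair (distance 0) makes that boundary shared between sisters
    with unknown provenance.
    """
    if left_pair.cls != CLASS_PARALLEL or right_pair.cls != CLASS_PARALLEL:
        raise ValueError("sister phasing requires parallel pairs on both sides")
    if left_pair.bp_a.orient != ORIENT_R or right_pair.bp_a.orient != ORIENT_L:
        raise ValueError(
            "expected an R/R pair on the left and an L/L pair on the right "
            f"(got {left_pair.bp_a.orient}/{right_pair.bp_a.orient})"
        )
    chrom = left_pair.bp_a.chrom
    a1, a2 = left_pair.bp_a.pos, left_pair.bp_b.pos
    b1, b2 = right_pair.bp_a.pos, right_pair.bp_b.pos
    if not (a2 <= b1):
        raise ValueError("left pair must lie left of right pair")
    s1 = RearrangedSegment(
        chrom, a1, b1,
        left_bp=left_pair.bp_a, right_bp=right_pair.bp_a,
        end_provenance={
            "left": UNKNOWN if left_pair.flush else P3,
            "right": UNKNOWN if right_pair.flush else P5,
        },
    )
    s2 = RearrangedSegment(
        chrom, a2, b2,
        left_bp=left_pair.bp_b, right_bp=right_pair.bp_b,
        end_provenance={
            "left": UNKNOWN if left_pair.flush else P5,
            "right": UNKNOWN if right_pair.flush else P3,
        },
    )
    s1.sister_partner, s2.sister_partner = 1, 0
    return s1, s2


def segment_copy_consistency(
    profile: CopyNumberProfile,
    segments: Sequence[RearrangedSegment],
    subclone: str,
    baseline: int = 0,
    haplotype: str | None = None,
    bin_size: int = DEFAULT_BIN,
) -> bool:
    """Check copy-number conservation: at every bin midpoint the profile
    copy equals ``baseline`` plus the number of reconstructed segment
    copies covering it (valid only where reconstruction is complete)."""
    for (chrom, hap), segs in profile.segments.items():
        if hap != haplotype:
            continue
        lo = min(s.start for s in segs)
        hi = max(s.end for s in segs)
        pos = lo + bin_size // 2
        while pos < hi:
            expected = baseline + sum(
                seg.copies.get(subclone, 0)
                for seg in segments
                if seg.chrom == chrom and seg.start <= pos <= seg.end
            )
            actual = profile.copy_at(chrom, pos, hap)
            if actual is not None and actual != expected:
                return False
            pos += bin_size
    return True
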