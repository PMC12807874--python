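"""Clustered-substitution detection and the 3'-overhang deamination test.

Resected DNA ends expose single-stranded 3' overhangs; cytosine
deamination on that ssDNA (APOBEC-style, TpC context) leaves clustered,
strand-coordinated substitutions confined to the offset interval between
a staggered (parallel) breakpoint pair.  The strand rule follows from the
geometry of resection: the overhang of a right-extending segment (R/R
pair, offset on the segment's left side) is reverse-strand DNA, read as
G>X on the forward strand; the overhang of a left-extending segment (L/L
pair, offset on the right side) is forward-strand DNA, read as C>X in the
TpC context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .adjacency import CLASS_PARALLEL, AdjacencyPair
from .core_model import ORIENT_L, ORIENT_R, Substitution

DEFAULT_MAX_GAP = 2_000
DEFAULT_MIN_SIZE = 3
DEFAULT_PURITY = 0.8
DEFAULT_CONTAINMENT = 0.9

CLASS_FWD_C = "fwd_C"   # C>T/G/A with a 5' T neighbour: forward-strand deamination
CLASS_REV_C = "rev_C"   # G>A/C/T with a 3' A neighbour: reverse-strand deamination
CLASS_MIXED = "mixed"
CLASS_OTHER = "other"
CLASS_UNKNOWN = "unknown"


@dataclass(frozen=True)
class SbsCluster:
    chrom: str
    members: tuple[Substitution, ...]

    @property
    def start(self) -> int:
        return self.members[0].pos

    @property
    def end(self) -> int:
        return self.members[-1].pos

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def detect_clusters(
    substitutions: Iterable[Substitution],
    max_gap: int = DEFAULT_MAX_GAP,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[SbsCluster]:
    """Maximal runs of substitutions with inter-mutation distance at most
    ``max_gap`` and at least ``min_size`` members.  Input order does not
    matter; substitutions are sorted internally."""
    subs = sorted(substitutions, key=lambda s: (s.chrom, s.pos))
    clusters = []
    run: list[Substitution] = []
    for s in subs + [None]:  # type: ignore[list-item]
        if (
            s is not None
            and run
            and s.chrom == run[-1].chrom
            and s.pos - run[-1].pos <= max_gap
        ):
            run.append(s)
            continue
        if len(run) >= min_size:
            clusters.append(SbsCluster(run[0].chrom, tuple(run)))
        run = [s] if s is not None else []
    return clusters


def _context_of(sub: Substitution, reference) -> str | None:
    if sub.context is not None:
        return sub.context.upper()
    if reference is None:
        return None
    seq = reference[sub.chrom]
    # pyfaidx FastaRecord and plain strings both slice 0-based
    tri = str(seq[sub.pos - 2 : sub.pos + 1]).upper()
    return tri if len(tri) == 3 else None


def classify_deamination(
    cluster: SbsCluster,
    reference=None,
    purity: float = DEFAULT_PURITY,
) -> str:
    """Classify a cluster's deamination strand.

    ``reference`` may be a ``pyfaidx.Fasta``, a mapping of chromosome name
    to sequence string, or None when members carry their own trinucleotide
    context.  Returns ``fwd_C`` when at least ``purity`` of members are
    C>X with a 5' T neighbour, ``rev_C`` for G>X with a 3' A neighbour,
    ``mixed`` when both patterns together dominate, ``other`` otherwise,
    and ``unknown`` when no context is available.
    """
    n_fwd = n_rev = n_ctx = 0
    for s in cluster.members:
        ctx = _context_of(s, reference)
        if ctx is None:
            continue
        n_ctx += 1
        if s.ref_base == "C" and s.alt_base in "TGA" and ctx[0] == "T":
            n_fwd += 1
        elif s.ref_base == "G" and s.alt_base in "ACT" and ctx[2] == "A":
            n_rev += 1
    if n_ctx == 0:
        return CLASS_UNKNOWN
    if n_fwd / n_ctx >= purity:
        return CLASS_FWD_C
    if n_rev / n_ctx >= purity:
        return CLASS_REV_C
    if (n_fwd + n_rev) / n_ctx >= purity and n_fwd and n_rev:
        return CLASS_MIXED
    return CLASS_OTHER


def expected_class_for_pair(pair: AdjacencyPair) -> tuple[str, str]:
    """(side, expected deamination class) for the offset interval of a
    staggered parallel pair: R/R pairs leave a left-side offset with
    reverse-strand deamination; L/L pairs a right-side offset with
    forward-strand deamination."""
    if pair.bp_a.orient == ORIENT_R:
        return "left", CLASS_REV_C
    return "right", CLASS_FWD_C


def offset_consistency(
    clusters: Sequence[SbsCluster],
    staggered_pairs: Sequence[AdjacencyPair],
    reference=None,
    containment: float = DEFAULT_CONTAINMENT,
    purity: float = DEFAULT_PURITY,
    near_window: int = 10_000,
) -> list[dict]:
    """Test each cluster near a staggered pair against the 3'-overhang
    deamination rule.

    The offset interval is [inner_pos, outer_pos], inclusive of both
    members.  A cluster is *consistent* when at least ``containment`` of
    its members fall inside the offset interval and its deamination class
    matches the side rule; deviations are reported, not dropped.
    Unoriented pairs are skipped.
    """
    rows = []
    pairs = [
        p for p in staggered_pairs
        if p.cls == CLASS_PARALLEL and p.bp_a.orient is not None and not p.flush
    ]
    for cluster in clusters:
        best: tuple[int, AdjacencyPair] | None = None
        for p in pairs:
            if p.bp_a.chrom != cluster.chrom:
                continue
            lo, hi = p.bp_a.pos, p.bp_b.pos
            if cluster.end < lo:
                d = lo - cluster.end
            elif cluster.start > hi:
                d = cluster.start - hi
            else:
                d = 0
            if d <= near_window and (best is None or d < best[0]):
                best = (d, p)
        if best is None:
            continue
        _, pair = best
        lo, hi = pair.bp_a.pos, pair.bp_b.pos
        inside = sum(lo <= s.pos <= hi for s in cluster.members)
        frac_inside = inside / len(cluster.members)
        side, expected = expected_class_for_pair(pair)
        observed = classify_deamination(cluster, reference, purity)
        rows.append(
            {
                "chrom": cluster.chrom,
                "cluster_start": cluster.start,
                "cluster_end": cluster.end,
                "n_members": len(cluster.members),
                "pair_pos_a": lo,
                "pair_pos_b": hi,
                "pair_orient": pair.bp_a.orient,
                "offset_side": side,
                "frac_in_offset": frac_inside,
                "expected_class": expected,
                "observed_class": observed,
                "consistent": frac_inside >= containment and observed == expected,
            }
        )
    return rows
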