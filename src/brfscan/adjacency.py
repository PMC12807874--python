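"""Breakpoint adjacency classification.

Two nearby breakpoints are classified by their orientation pattern in
coordinate order:

* ``(R, L)`` — insertion/overlap adjacency: the interval between them is
  an inserted or over-replicated segment;
* ``(L, R)`` — gapped adjacency: a small deleted interval, the signature
  of end ligation before replication (G1 c-NHEJ);
* ``(R, R)`` or ``(L, L)`` — parallel adjacency: two breakpoints with the
  same orientation, the signature of a single resected DNA end replicated
  into two "sister" ends.

Classification enforces an exclusion ordering: breakpoints consumed by an
insertion/overlap pair are removed before gapped or parallel
classification, because insertion breakpoints all fall within the
threshold distance but arise from a different process.  Gapped and
parallel classification then run independently on the surviving set (a
breakpoint may be a member of one gapped pair *and* one parallel group;
their intersection defines reciprocal configurations).

Runs of three or more same-orientation breakpoints are grouped by single
linkage; every consecutive pair within a group is reported as a parallel
pair.  Pairs at zero distance are retained and flagged ``flush``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_model import ORIENT_L, ORIENT_R, Breakpoint, Junction

DEFAULT_THRESHOLD = 20_000

CLASS_INSERTION_OVERLAP = "insertion_overlap"
CLASS_GAPPED = "gapped"
CLASS_PARALLEL = "parallel"

KIND_NESTED_DELETIONS = "nested_deletions"
KIND_RECIPROCAL_FOLDBACKS = "reciprocal_foldbacks"
KIND_MIXED_TRANSLOCATION = "mixed_translocation"


@dataclass(frozen=True)
class AdjacencyPair:
    cls: str
    bp_a: Breakpoint  # coordinate-ordered: pos_a <= pos_b
    bp_b: Breakpoint
    distance: int
    flush: bool
    group_id: str | None = None

    @property
    def key(self) -> tuple:
        return (self.cls, self.bp_a.chrom, self.bp_a.pos, self.bp_a.orient,
                self.bp_b.pos, self.bp_b.orient)


@dataclass(frozen=True)
class ParallelGroup:
    group_id: str
    sample_id: str
    chrom: str
    orientation: str
    members: tuple[Breakpoint, ...]  # position-sorted, >= 2 members

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].pos, self.members[-1].pos)


@dataclass(frozen=True)
class ReciprocalConfiguration:
    kind: str
    gapped_pair: AdjacencyPair
    left_group: ParallelGroup | None   # L-orientation side (extends left)
    right_group: ParallelGroup | None  # R-orientation side (extends right)
    partial: bool


@dataclass
class AdjacencyCatalog:
    """Result of :func:`classify_adjacency`."""

    pairs: list[AdjacencyPair]
    groups: list[ParallelGroup]
    surviving: list[Breakpoint]  # oriented breakpoints after insertion/overlap exclusion
    skipped_unoriented: int
    threshold: int
    counts: Mapping[str, int] = field(default_factory=dict)

    def pairs_of(self, cls: str) -> list[AdjacencyPair]:
        return [p for p in self.pairs if p.cls == cls]


def _bp_sort_key(bp: Breakpoint) -> tuple:
    return (bp.sample_id, bp.chrom, bp.pos, bp.orient or "", bp.junction_id)


def _greedy_match(candidates: list[tuple[int, Breakpoint, Breakpoint]]) -> list[tuple[Breakpoint, Breakpoint, int]]:
    """Nearest-first matching: candidates sorted by (distance, coords) and
    accepted when both members are still free.  Deterministic."""
    candidates.sort(key=lambda c: (c[0], _bp_sort_key(c[1]), _bp_sort_key(c[2])))
    used: set[int] = set()
    out = []
    for d, a, b in candidates:
        ka, kb = id(a), id(b)
        if ka in used or kb in used:
            continue
        used.update((ka, kb))
        out.append((a, b, d))
    return out


def _pattern_candidates(
    bps: Sequence[Breakpoint], orient_a: str, orient_b: str, threshold: int
) -> list[tuple[int, Breakpoint, Breakpoint]]:
    """All coordinate-ordered pairs (a before b) with the given orientation
    pattern within the threshold, via a sorted sliding window."""
    out = []
    n = len(bps)
    for i in range(n):
        a = bps[i]
        for j in range(i + 1, n):
            b = bps[j]
            if b.pos - a.pos > threshold:
                break
            first, second = a, b
            if a.pos == b.pos and (a.orient or "") > (b.orient or ""):
                first, second = b, a  # tie-break: L sorts before R at equal pos
            if first.orient == orient_a and second.orient == orient_b:
                out.append((second.pos - first.pos, first, second))
    return out


def classify_adjacency(
    breakpoints: Iterable[Breakpoint],
    threshold: int = DEFAULT_THRESHOLD,
) -> AdjacencyCatalog:
    """Classify breakpoint adjacency within each sample and chromosome.

    Returns a catalog of insertion/overlap, gapped and parallel pairs plus
    parallel groups and the surviving (post-exclusion) breakpoint set.
    Unoriented breakpoints are skipped and counted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    all_bps = list(breakpoints)
    oriented = [bp for bp in all_bps if bp.orient is not None]
    skipped = len(all_bps) - len(oriented)
    by_group: dict[tuple[str, str], list[Breakpoint]] = {}
    for bp in oriented:
        by_group.setdefault((bp.sample_id, bp.chrom), []).append(bp)

    pairs: list[AdjacencyPair] = []
    groups: list[ParallelGroup] = []
    surviving: list[Breakpoint] = []
    n_groups = 0

    for (sample, chrom), bps in sorted(by_group.items()):
        bps.sort(key=_bp_sort_key)

        # stage 1: insertion/overlap (R, L) — consumed before anything else
        io_candidates = _pattern_candidates(bps, ORIENT_R, ORIENT_L, threshold)
        io_matched = _greedy_match(io_candidates)
        consumed = {id(bp) for a, b, _ in io_matched for bp in (a, b)}
        for a, b, d in io_matched:
            pairs.append(AdjacencyPair(CLASS_INSERTION_OVERLAP, a, b, d, d == 0))
        remaining = [bp for bp in bps if id(bp) not in consumed]
        surviving.extend(remaining)

        # stage 2: gapped (L, R) on the surviving set
        gap_candidates = _pattern_candidates(remaining, ORIENT_L, ORIENT_R, threshold)
        for a, b, d in _greedy_match(gap_candidates):
            pairs.append(AdjacencyPair(CLASS_GAPPED, a, b, d, d == 0))

        # stage 3: parallel — single-linkage runs per orientation
        for orient in (ORIENT_L, ORIENT_R):
            run: list[Breakpoint] = []
            members = [bp for bp in remaining if bp.orient == orient]
            for bp in members + [None]:  # type: ignore[list-item]
                if bp is not None and (not run or bp.pos - run[-1].pos <= threshold):
                    run.append(bp)
                    continue
                if len(run) >= 2:
                    n_groups += 1
                    gid = f"{sample or 'catalog'}_{chrom}_{orient}_{n_groups}"
                    groups.append(ParallelGroup(gid, sample, chrom, orient, tuple(run)))
                    for x, y in zip(run, run[1:]):
                        d = y.pos - x.pos
                        pairs.append(AdjacencyPair(CLASS_PARALLEL, x, y, d, d == 0, gid))
                run = [bp] if bp is not None else []

    counts = {
        CLASS_INSERTION_OVERLAP: sum(1 for p in pairs if p.cls == CLASS_INSERTION_OVERLAP),
        CLASS_GAPPED: sum(1 for p in pairs if p.cls == CLASS_GAPPED),
        CLASS_PARALLEL: sum(1 for p in pairs if p.cls == CLASS_PARALLEL),
        "parallel_groups": len(groups),
        "breakpoints": len(oriented),
    }
    surviving.sort(key=_bp_sort_key)
    return AdjacencyCatalog(pairs, groups, surviving, skipped, threshold, counts)


def detect_foldbacks(
    junctions: Iterable[Junction], threshold: int = DEFAULT_THRESHOLD
) -> list[tuple[Junction, int, str]]:
    """Foldback junctions: intrachromosomal, same-orientation breakpoint
    pairs within the threshold distance.  Returns (junction, distance,
    orientation) tuples."""
    out = []
    for j in junctions:
        if not j.intrachromosomal:
            continue
        if j.bp1.orient is None or j.bp1.orient != j.bp2.orient:
            continue
        d = abs(j.bp2.pos - j.bp1.pos)
        if d <= threshold:
            out.append((j, d, j.bp1.orient))
    return out


def _junction_is_deletion(j: Junction) -> bool:
    return (
        j.intrachromosomal
        and j.bp1.orient == ORIENT_L
        and j.bp2.orient == ORIENT_R
        and j.bp1.pos <= j.bp2.pos
    )


def _junction_is_foldback(j: Junction, threshold: int) -> bool:
    return (
        j.intrachromosomal
        and j.bp1.orient is not None
        and j.bp1.orient == j.bp2.orient
        and abs(j.bp2.pos - j.bp1.pos) <= threshold
    )


def find_reciprocal(
    catalog: AdjacencyCatalog,
    junctions: Sequence[Junction] | None = None,
) -> list[ReciprocalConfiguration]:
    """Intersect parallel groups with gapped pairs to find reciprocal
    configurations: an inner gapped pair whose members also belong to
    parallel groups on either side identifies the two reciprocal ends of
    an ancestral double-strand break.

    When junctions are supplied, the configuration kind is refined by
    junction topology (nested deletions, reciprocal foldbacks of opposite
    orientation, or a mixed/translocation pattern); configurations with
    parallel support on only one side are labeled partial.
    """
    membership: dict[tuple, ParallelGroup] = {}
    for g in catalog.groups:
        for bp in g.members:
            membership[(bp.sample_id, bp.chrom, bp.pos, bp.orient, bp.junction_id)] = g

    jmap = {j.id: j for j in junctions} if junctions else {}
    out = []
    for pair in catalog.pairs_of(CLASS_GAPPED):
        bp_l, bp_r = pair.bp_a, pair.bp_b  # orientations (L, R)
        key_l = (bp_l.sample_id, bp_l.chrom, bp_l.pos, bp_l.orient, bp_l.junction_id)
        key_r = (bp_r.sample_id, bp_r.chrom, bp_r.pos, bp_r.orient, bp_r.junction_id)
        g_left = membership.get(key_l)
        g_right = membership.get(key_r)
        if g_left is None and g_right is None:
            continue
        partial = g_left is None or g_right is None
        kind = KIND_MIXED_TRANSLOCATION
        if not partial and jmap:
            involved_ids = {bp.junction_id for bp in (*g_left.members, *g_right.members)}
            involved = [jmap[i] for i in involved_ids if i in jmap]
            if involved and all(_junction_is_deletion(j) for j in involved):
                kind = KIND_NESTED_DELETIONS
            elif (
                involved
                and all(_junction_is_foldback(j, catalog.threshold) for j in involved)
                and {j.bp1.orient for j in involved} == {ORIENT_L, ORIENT_R}
            ):
                kind = KIND_RECIPROCAL_FOLDBACKS
        out.append(ReciprocalConfiguration(kind, pair, g_left, g_right, partial))
    return out
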