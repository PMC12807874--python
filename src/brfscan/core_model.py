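"""Data model and file I/O for rearrangement-breakpoint analysis.

Conventions
-----------
Coordinates are 1-based inclusive throughout. A breakpoint's ``pos`` is the
terminal retained base of the rearranged sequence on the side indicated by
``orient``:

``L``
    the retained sequence lies to the *left* of (and including) ``pos``; at
    a copy-number profile this is a down-transition when reading left to
    right.
``R``
    the retained sequence lies to the *right* of (and including) ``pos``;
    an up-transition.

Published structural-variant callers disagree on the sign convention used
for breakpoint "strands", so strand-to-orientation mapping is dialect
dependent and recorded in every file written by this module.  BEDPE input
is converted from 0-based half-open coordinates at the boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

ORIENT_L = "L"
ORIENT_R = "R"

#: strand-letter -> orientation-token maps, per caller dialect
DIALECTS: Mapping[str, Mapping[str, str]] = {
    "caller-default": {"+": ORIENT_L, "-": ORIENT_R},
    "inverted": {"+": ORIENT_R, "-": ORIENT_L},
}

CANONICAL_DIALECT = "caller-default"


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Breakpoint:
    """One side of a rearrangement junction.

    ``pos`` is the last retained base (1-based); ``orient`` says on which
    side the retained sequence lies (see module docstring).  ``orient`` may
    be ``None`` for breakpoints read from copy-number data before
    orientation assignment.
    """

    chrom: str
    pos: int
    orient: str | None = None
    sample_id: str = ""
    junction_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"breakpoint position must be >= 1, got {self.pos}")
        if self.orient not in (ORIENT_L, ORIENT_R, None):
            raise FormatError(f"orientation must be L or R, got {self.orient!r}")


@dataclass(frozen=True)
class Insertion:
    """A fragment inserted at a rearrangement junction.

    Origin coordinates are 1-based inclusive; ``origin_strand`` is the
    strand of the inserted sequence as it appears at the destination
    junction ('fwd', 'rev' or 'unknown').
    """

    dest_junction_id: str
    index_in_chain: int
    origin_chrom: str | None = None
    origin_start: int | None = None
    origin_end: int | None = None
    origin_strand: str = "unknown"
    length: int = 0
    nearest_ancestral_bp: tuple[int, str] | None = None
    sub_junction_homology: int = 0
    sub_junction_untemplated: str = ""

    @property
    def has_origin(self) -> bool:
        return self.origin_chrom is not None


@dataclass(frozen=True)
class Junction:
    """An ordered pair of breakpoints plus junction-level annotations."""

    id: str
    bp1: Breakpoint
    bp2: Breakpoint
    inserted_fragments: tuple[Insertion, ...] = ()
    homology_len: int = 0
    untemplated_seq: str = ""

    def __post_init__(self) -> None:
        if self.homology_len < 0:
            raise FormatError("homology length must be >= 0")
        if (self.bp1.chrom, self.bp1.pos) > (self.bp2.chrom, self.bp2.pos):
            raise FormatError(
                f"junction {self.id}: bp1 must not sort after bp2 "
                f"({self.bp1.chrom}:{self.bp1.pos} > {self.bp2.chrom}:{self.bp2.pos})"
            )

    @property
    def breakpoints(self) -> tuple[Breakpoint, Breakpoint]:
        return (self.bp1, self.bp2)

    @property
    def intrachromosomal(self) -> bool:
        return self.bp1.chrom == self.bp2.chrom

    @property
    def span(self) -> int | None:
        return self.bp2.pos - self.bp1.pos if self.intrachromosomal else None


def make_junction(
    id: str,
    bp1: Breakpoint,
    bp2: Breakpoint,
    inserted_fragments: Sequence[Insertion] = (),
    homology_len: int = 0,
    untemplated_seq: str = "",
) -> Junction:
    """Build a junction, normalizing breakpoint order to (chrom, pos)."""
    if (bp1.chrom, bp1.pos) > (bp2.chrom, bp2.pos):
        bp1, bp2 = bp2, bp1
    bp1 = replace(bp1, junction_id=id)
    bp2 = replace(bp2, junction_id=id)
    return Junction(id, bp1, bp2, tuple(inserted_fragments), homology_len, untemplated_seq)


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    copy: float
    haplotype: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"segment start {self.start} > end {self.end}")
        if self.copy < 0:
            raise FormatError("copy number must be non-negative")

    @property
    def is_integer(self) -> bool:
        return float(self.copy).is_integer()


@dataclass(frozen=True)
class Substitution:
    """Single-base substitution; ``context`` is the reference trinucleotide
    centred on ``pos`` (forward strand), when known."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    context: str | None = None

    def __post_init__(self) -> None:
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise FormatError("substitutions must be single-base")
        if self.ref_base == self.alt_base:
            raise FormatError("ref and alt must differ")


class CopyNumberProfile:
    """Sorted, non-overlapping copy-number segments per (chrom, haplotype).

    Gaps between segments are permitted and recorded in :attr:`gaps`.
    """

    def __init__(self, segments: Iterable[CopyNumberSegment]):
        by_key: dict[tuple[str, str | None], list[CopyNumberSegment]] = {}
        for seg in segments:
            by_key.setdefault((seg.chrom, seg.haplotype), []).append(seg)
        self.segments: dict[tuple[str, str | None], list[CopyNumberSegment]] = {}
        self.gaps: list[tuple[str, str | None, int, int]] = []
        self._trees: dict[tuple[str, str | None], IntervalTree] = {}
        for key, segs in sorted(by_key.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
            segs.sort(key=lambda s: (s.start, s.end))
            collisions = [
                (a, b) for a, b in zip(segs, segs[1:]) if b.start <= a.end
            ]
            if collisions:
                desc = "; ".join(
                    f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
                    for a, b in collisions
                )
                raise FormatError(f"overlapping copy-number segments: {desc}")
            for a, b in zip(segs, segs[1:]):
                if b.start > a.end + 1:
                    self.gaps.append((key[0], key[1], a.end + 1, b.start - 1))
            self.segments[key] = segs
            tree = IntervalTree()
            for seg in segs:
                tree[seg.start : seg.end + 1] = seg
            self._trees[key] = tree

    @property
    def non_integer(self) -> bool:
        """True when any segment has a fractional copy state (bulk
        subclonal mixtures)."""
        return any(
            not seg.is_integer for segs in self.segments.values() for seg in segs
        )

    def haplotypes(self, chrom: str) -> list[str | None]:
        return [hap for (c, hap) in self.segments if c == chrom]

    def copy_at(self, chrom: str, pos: int, haplotype: str | None = "sum") -> float | None:
        """Copy number at ``pos``.  With ``haplotype='sum'`` (default) the
        haplotype copies are summed; returns None inside a gap."""
        if haplotype != "sum":
            hits = self._trees.get((chrom, haplotype), IntervalTree())[pos]
            return next(iter(hits)).data.copy if hits else None
        total, found = 0.0, False
        for (c, hap), tree in self._trees.items():
            if c != chrom:
                continue
            hits = tree[pos]
            if hits:
                total += next(iter(hits)).data.copy
                found = True
        return total if found else None

    def all_segments(self) -> list[CopyNumberSegment]:
        return [seg for segs in self.segments.values() for seg in segs]

    def breakpoint_positions(self, chrom: str, haplotype: str | None = None) -> list[tuple[int, str]]:
        """Copy-number transition positions for one haplotype as
        ``(pos, orient)`` pairs, following the orientation convention."""
        segs = self.segments.get((chrom, haplotype), [])
        out = []
        for a, b in zip(segs, segs[1:]):
            if b.start == a.end + 1 and a.copy != b.copy:
                if b.copy > a.copy:
                    out.append((b.start, ORIENT_R))
                else:
                    out.append((a.end, ORIENT_L))
        return out


# ---------------------------------------------------------------------------
# BEDPE junctions
# ---------------------------------------------------------------------------

_BEDPE_COLS = 10  # chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2


def _orient_to_strand(orient: str, dialect: str) -> str:
    for strand, o in DIALECTS[dialect].items():
        if o == orient:
            return strand
    raise KeyError(orient)


def _encode_insertions(fragments: Sequence[Insertion]) -> str:
    if not fragments:
        return "."
    parts = []
    for f in fragments:
        strand = {"fwd": "+", "rev": "-"}.get(f.origin_strand, ".")
        if f.has_origin:
            parts.append(f"{f.origin_chrom}:{f.origin_start}-{f.origin_end}:{strand}:{f.length}")
        else:
            parts.append(f".:.-.:{strand}:{f.length}")
    return ";".join(parts)


def _decode_insertions(text: str, junction_id: str) -> tuple[Insertion, ...]:
    if text in (".", ""):
        return ()
    out = []
    for i, part in enumerate(text.split(";"), start=1):
        m = re.match(r"^(.+):(\d+|\.)-(\d+|\.):([+\-.]):(\d+)$", part)
        if not m:
            raise FormatError(f"cannot parse insertion field {part!r}")
        chrom, start, end, strand, length = m.groups()
        has_origin = chrom != "." and start != "."
        out.append(
            Insertion(
                dest_junction_id=junction_id,
                index_in_chain=i,
                origin_chrom=chrom if has_origin else None,
                origin_start=int(start) if has_origin else None,
                origin_end=int(end) if has_origin else None,
                origin_strand={"+": "fwd", "-": "rev"}.get(strand, "unknown"),
                length=int(length),
            )
        )
    return tuple(out)


def read_junctions(path: str | Path, dialect: str = CANONICAL_DIALECT, sample_id: str = "") -> list[Junction]:
    """Read a BEDPE junction catalog (or a breakend VCF, detected by
    extension) into :class:`Junction` records.

    BEDPE columns 1-10 follow the common caller layout; optional columns
    11-13 carry microhomology length, untemplated sequence and an encoded
    insertion list as written by :func:`write_junctions`.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return read_junctions_vcf(path, dialect=dialect, sample_id=sample_id)
    if dialect not in DIALECTS:
        raise FormatError(f"unknown strand dialect {dialect!r}; known: {sorted(DIALECTS)}")
    strand_map = DIALECTS[dialect]
    junctions: list[Junction] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            cols = line.split("\t")
            if len(cols) < _BEDPE_COLS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_BEDPE_COLS} columns "
                    f"(missing strand columns 9-10), got {len(cols)}"
                )
            chrom1, start1, end1, chrom2, start2, end2, name = cols[:7]
            strand1, strand2 = cols[8], cols[9]
            for label, s in (("strand1", strand1), ("strand2", strand2)):
                if s not in strand_map:
                    raise FormatError(
                        f"{path}:{lineno}: column {label} has unknown strand {s!r}"
                    )
            # BEDPE is 0-based half-open: `end` is the 1-based coordinate.
            pos1, pos2 = int(end1), int(end2)
            if pos1 < 1 or pos2 < 1:
                raise FormatError(f"{path}:{lineno}: coordinate < 1")
            jid = name if name not in (".", "") else f"bedpe_{lineno}"
            homlen = int(cols[10]) if len(cols) > 10 and cols[10] != "." else 0
            untemplated = cols[11] if len(cols) > 11 and cols[11] != "." else ""
            fragments = _decode_insertions(cols[12], jid) if len(cols) > 12 else ()
            bp1 = Breakpoint(chrom1, pos1, strand_map[strand1], sample_id, jid)
            bp2 = Breakpoint(chrom2, pos2, strand_map[strand2], sample_id, jid)
            junctions.append(make_junction(jid, bp1, bp2, fragments, homlen, untemplated))
    if n_lines == 0:
        log.warning("no junction records in %s", path)
    junctions.sort(key=lambda j: (j.bp1.chrom, j.bp1.pos, j.bp1.orient or "", j.id))
    return junctions


def write_junctions(
    path: str | Path,
    junctions: Sequence[Junction],
    dialect: str = CANONICAL_DIALECT,
    params: Mapping[str, object] | None = None,
) -> None:
    if dialect not in DIALECTS:
        raise FormatError(f"unknown strand dialect {dialect!r}")
    header = {"dialect": dialect, **(params or {})}
    ordered = sorted(junctions, key=lambda j: (j.bp1.chrom, j.bp1.pos, j.bp1.orient or "", j.id))
    with open(path, "w") as fh:
        fh.write("#brfscan bedpe " + " ".join(f"{k}={v}" for k, v in header.items()) + "\n")
        for j in ordered:
            row = [
                j.bp1.chrom, str(j.bp1.pos - 1), str(j.bp1.pos),
                j.bp2.chrom, str(j.bp2.pos - 1), str(j.bp2.pos),
                j.id, ".",
                _orient_to_strand(j.bp1.orient, dialect),
                _orient_to_strand(j.bp2.orient, dialect),
                str(j.homology_len),
                j.untemplated_seq or ".",
                _encode_insertions(j.inserted_fragments),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF breakend pairs
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"^(?:(?P<t1>[A-Za-z.]+)(?P<b1>[\[\]])(?P<m1>[^\[\]]+)(?P=b1)"
                     r"|(?P<b2>[\[\]])(?P<m2>[^\[\]]+)(?P=b2)(?P<t2>[A-Za-z.]+))$")


def read_junctions_vcf(path: str | Path, dialect: str = CANONICAL_DIALECT, sample_id: str = "") -> list[Junction]:
    """Read VCF 4.x breakend pairs (paired via INFO/MATEID).

    The local breakend orientation is taken from the ALT bracket form:
    REF base before the bracket means the retained sequence lies left of
    POS (orientation L); after means right (R).  ``dialect`` is accepted
    for interface symmetry but breakend ALT syntax is unambiguous.
    """
    import pysam

    records: dict[str, tuple[str, int, str, str | None]] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else ""
            m = _BND_RE.match(alt)
            if not m:
                continue
            orient = ORIENT_L if m.group("t1") else ORIENT_R
            mate = rec.info.get("MATEID")
            if isinstance(mate, tuple):
                mate = mate[0]
            records[rec.id] = (rec.chrom, rec.pos, orient, mate)
    junctions = []
    done: set[str] = set()
    for vid, (chrom, pos, orient, mate) in sorted(records.items()):
        if vid in done or mate is None or mate not in records:
            continue
        mchrom, mpos, morient, _ = records[mate]
        done.update((vid, mate))
        jid = vid.rsplit("_", 1)[0] if vid.endswith(("_1", "_2")) else vid
        junctions.append(
            make_junction(
                jid,
                Breakpoint(chrom, pos, orient, sample_id, jid),
                Breakpoint(mchrom, mpos, morient, sample_id, jid),
            )
        )
    junctions.sort(key=lambda j: (j.bp1.chrom, j.bp1.pos, j.bp1.orient or "", j.id))
    return junctions


def write_junctions_vcf(path: str | Path, junctions: Sequence[Junction], params: Mapping[str, object] | None = None) -> None:
    chroms = sorted({bp.chrom for j in junctions for bp in j.breakpoints})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=brfscan" + "".join(f" {k}={v}" for k, v in (params or {}).items()) + "\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for j in sorted(junctions, key=lambda j: (j.bp1.chrom, j.bp1.pos, j.id)):
            for this, other, tag in ((j.bp1, j.bp2, "1"), (j.bp2, j.bp1, "2")):
                bracket = "]" if other.orient == ORIENT_L else "["
                mate_loc = f"{bracket}{other.chrom}:{other.pos}{bracket}"
                alt = "N" + mate_loc if this.orient == ORIENT_L else mate_loc + "N"
                info = f"SVTYPE=BND;MATEID={j.id}_{'2' if tag == '1' else '1'}"
                rows.append((this.chrom, this.pos, f"{j.id}_{tag}", alt, info))
        for chrom, pos, vid, alt, info in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t{vid}\tN\t{alt}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# copy-number segments (BED + copy column)
# ---------------------------------------------------------------------------


def read_cn_segments(path: str | Path) -> CopyNumberProfile:
    """Read a BED-like table (chrom, start, end, copy[, haplotype]) into a
    sorted, validated profile.  BED coordinates are 0-based half-open."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            chrom, start, end, copy = cols[:4]
            hap = cols[4] if len(cols) > 4 and cols[4] != "." else None
            copy_val = float(copy)
            segments.append(
                CopyNumberSegment(chrom, int(start) + 1, int(end), copy_val, hap)
            )
    profile = CopyNumberProfile(segments)
    if profile.non_integer:
        log.info("profile %s contains non-integer copy states (subclonal mixture)", path)
    return profile


def write_cn_segments(path: str | Path, profile: CopyNumberProfile, params: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("#brfscan cn-bed " + " ".join(f"{k}={v}" for k, v in (params or {}).items()) + "\n")
        for (chrom, hap), segs in profile.segments.items():
            for seg in segs:
                copy = int(seg.copy) if seg.is_integer else seg.copy
                fh.write(f"{chrom}\t{seg.start - 1}\t{seg.end}\t{copy}\t{hap or '.'}\n")


# ---------------------------------------------------------------------------
# substitutions (minimal VCF)
# ---------------------------------------------------------------------------


def read_substitutions(path: str | Path) -> list[Substitution]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if len(rec.ref) != 1 or not rec.alts or len(rec.alts[0]) != 1:
                continue
            ctx = rec.info.get("TNC")
            out.append(Substitution(rec.chrom, rec.pos, rec.ref, rec.alts[0], ctx))
    out.sort(key=lambda s: (s.chrom, s.pos))
    return out


def write_substitutions(path: str | Path, subs: Sequence[Substitution], params: Mapping[str, object] | None = None) -> None:
    chroms = sorted({s.chrom for s in subs})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=brfscan" + "".join(f" {k}={v}" for k, v in (params or {}).items()) + "\n")
        fh.write('##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(subs, key=lambda s: (s.chrom, s.pos)):
            info = f"TNC={s.context}" if s.context else "."
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# orientation from copy number
# ---------------------------------------------------------------------------


@dataclass
class OrientationReport:
    assigned: int = 0
    flat: list[Breakpoint] = field(default_factory=list)
    ambiguous: list[Breakpoint] = field(default_factory=list)
    outside: list[Breakpoint] = field(default_factory=list)


def orient_from_copy_number(
    breakpoints: Sequence[Breakpoint],
    profile: CopyNumberProfile,
    haplotype: str | None = "sum",
) -> tuple[list[Breakpoint], OrientationReport]:
    """Assign orientations from copy-number transitions.

    A breakpoint at ``p`` gets R when copy rises at p (copy(p) > copy(p-1))
    and L when copy falls after p (copy(p) > copy(p+1)).  Flat positions
    are left unoriented and flagged; positions where both rules fire
    (coincident boundaries) are flagged ambiguous; positions outside the
    profile are flagged and not assigned.  Idempotent: already-oriented
    breakpoints pass through unchanged.
    """
    out: list[Breakpoint] = []
    report = OrientationReport()
    for bp in breakpoints:
        if bp.orient is not None:
            out.append(bp)
            continue
        here = profile.copy_at(bp.chrom, bp.pos, haplotype)
        left = profile.copy_at(bp.chrom, bp.pos - 1, haplotype) if bp.pos > 1 else None
        right = profile.copy_at(bp.chrom, bp.pos + 1, haplotype)
        if here is None:
            report.outside.append(bp)
            out.append(bp)
            continue
        up = left is not None and here > left
        down = right is not None and here > right
        if up and down:
            report.ambiguous.append(bp)
            out.append(bp)
        elif up:
            out.append(replace(bp, orient=ORIENT_R))
            report.assigned += 1
        elif down:
            out.append(replace(bp, orient=ORIENT_L))
            report.assigned += 1
        else:
            report.flat.append(bp)
            out.append(bp)
    return out, report
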