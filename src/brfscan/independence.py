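"""Breakpoint-independence scoring for adjacent parallel breakpoints.

Two parallel breakpoints at distance ``d`` derived from independent breaks
on an ancestral segment of length ``L`` would co-occur that closely with
probability ``(d/L)^k`` (``k`` independent additional breaks falling
within ``d`` downstream of the first, one-sided).  A small probability
argues that the pair instead derives from replication of a single resected
DNA end.

For real catalogs the ancestral segment length is unknown; it is bounded
below by the distance from the pair to the nearest surviving
opposite-orientation breakpoint on the side the segment extends (right for
R/R pairs, left for L/L pairs).  The resulting ratio is therefore an upper
bound of the true breakpoint distance ratio.  ``L`` is anchored at the
inner (segment-proximal) member of the pair.  When no opposite breakpoint
exists on that side, the distance to the chromosome end is used and the
pair is flagged censored; censored pairs are reported but excluded from
flag counts.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .adjacency import CLASS_PARALLEL, AdjacencyCatalog, AdjacencyPair
from .core_model import ORIENT_L, ORIENT_R, Breakpoint

DEFAULT_ALPHA = 0.05

SOURCE_OPPOSITE = "opposite_bp"
SOURCE_CHROM_END = "chrom_end"
SOURCE_KNOWN = "known_segment"


@dataclass(frozen=True)
class IndependenceQuery:
    d: float           # distance between the parallel breakpoints (bp)
    L: float           # ancestral segment length (bp)
    k: int = 1         # number of additional independent breaks
    L_is_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.L <= 0:
            raise ValueError("L must be positive")


@dataclass(frozen=True)
class IndependenceResult:
    r: float
    p_indep: float
    upper_bound: bool


@dataclass(frozen=True)
class PairScore:
    pair: AdjacencyPair
    L: float | None
    L_source: str | None
    r: float | None
    k: int
    p_indep: float | None
    non_independent: bool | None  # None when unscorable or censored


def independence_probability(query: IndependenceQuery) -> IndependenceResult:
    """P(k additional independent breaks each fall within d of the first)
    = (d/L)^k.  Errors when d > L (violates the segment-length invariant)."""
    if query.d > query.L:
        raise ValueError(f"d ({query.d}) exceeds segment length L ({query.L})")
    r = query.d / query.L
    return IndependenceResult(r=r, p_indep=r ** query.k, upper_bound=query.L_is_lower_bound)


def estimate_segment_length(
    pair: AdjacencyPair,
    breakpoints: Sequence[Breakpoint],
    chrom_bounds: Mapping[str, int] | None = None,
) -> tuple[float | None, str | None]:
    """Lower-bound the ancestral segment length of a parallel pair.

    ``breakpoints`` must be the post-exclusion (surviving) set.  For an
    R/R pair the segment extends right: L is the distance from the inner
    (rightmost) member to the first L breakpoint to the right.  For an
    L/L pair, symmetrically to the left.  Falls back to the chromosome
    end (censored) and returns (None, None) when unscorable.
    """
    if pair.cls != CLASS_PARALLEL:
        raise ValueError("segment length is defined for parallel pairs only")
    orient = pair.bp_a.orient
    opposite = ORIENT_L if orient == ORIENT_R else ORIENT_R
    positions = sorted(
        bp.pos
        for bp in breakpoints
        if bp.chrom == pair.bp_a.chrom
        and bp.sample_id == pair.bp_a.sample_id
        and bp.orient == opposite
    )
    lo, hi = pair.bp_a.pos, pair.bp_b.pos
    between = positions[bisect_right(positions, lo) : bisect_left(positions, hi)]
    assert not between, (
        "opposite-orientation breakpoint inside a parallel pair; "
        "exclusion ordering was not applied"
    )
    if orient == ORIENT_R:
        inner = hi
        idx = bisect_right(positions, inner)
        if idx < len(positions):
            return float(positions[idx] - inner), SOURCE_OPPOSITE
        if chrom_bounds and pair.bp_a.chrom in chrom_bounds:
            return float(chrom_bounds[pair.bp_a.chrom] - inner), SOURCE_CHROM_END
    else:
        inner = lo
        idx = bisect_left(positions, inner)
        if idx > 0:
            return float(inner - positions[idx - 1]), SOURCE_OPPOSITE
        # the left "chromosome end" is coordinate 1, always known
        return float(inner - 1), SOURCE_CHROM_END
    return None, None


def flag_non_independent(
    catalog: AdjacencyCatalog,
    alpha: float = DEFAULT_ALPHA,
    k: int = 1,
    chrom_bounds: Mapping[str, int] | None = None,
    known_lengths: Mapping[tuple, float] | None = None,
) -> tuple[list[PairScore], dict]:
    """Score every parallel pair in the catalog and flag those whose
    independence probability is strictly below ``alpha``.

    ``known_lengths`` maps ``pair.key`` to an exactly known ancestral
    segment length (subclone-resolved mode); otherwise L is estimated from
    the surviving breakpoint set.  The summary reports counts in the form
    "x of n scorable pairs flagged"; censored pairs are reported but not
    counted.
    """
    scores: list[PairScore] = []
    n_flagged = n_scorable = n_censored = n_unscorable = 0
    for pair in catalog.pairs_of(CLASS_PARALLEL):
        if known_lengths is not None and pair.key in known_lengths:
            L, source = float(known_lengths[pair.key]), SOURCE_KNOWN
        else:
            L, source = estimate_segment_length(pair, catalog.surviving, chrom_bounds)
        if L is None or L <= 0 or pair.distance > L:
            scores.append(PairScore(pair, L, source, None, k, None, None))
            n_unscorable += 1
            continue
        res = independence_probability(
            IndependenceQuery(pair.distance, L, k, L_is_lower_bound=source != SOURCE_KNOWN)
        )
        if source == SOURCE_CHROM_END:
            scores.append(PairScore(pair, L, source, res.r, k, res.p_indep, None))
            n_censored += 1
            continue
        flagged = res.p_indep < alpha
        scores.append(PairScore(pair, L, source, res.r, k, res.p_indep, flagged))
        n_scorable += 1
        n_flagged += flagged
    summary = {
        "alpha": alpha,
        "k": k,
        "pairs": len(scores),
        "scorable": n_scorable,
        "flagged": n_flagged,
        "censored": n_censored,
        "unscorable": n_unscorable,
        "statement": f"{n_flagged} of {n_scorable} pairs of adjacent parallel "
                     f"breakpoints have independence probability < {alpha}",
    }
    return scores, summary


def calibrate_uniform_null(
    n_reps: int,
    alpha: float = DEFAULT_ALPHA,
    k: int = 1,
    segment_length: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo calibration of the flagging rule under the uniform null.

    Each replicate places one additional independent break uniformly on a
    known ancestral segment; the pair distance is the break's offset from
    the segment end.  With k = 1 the independence probability is then
    uniform on [0, 1), so the flagged fraction estimates ``alpha``.
    """
    rng = rng or np.random.default_rng()
    offsets = rng.integers(0, segment_length, size=n_reps)
    flagged = 0
    for d in offsets:
        res = independence_probability(IndependenceQuery(float(d), float(segment_length), k))
        flagged += res.p_indep < alpha
    return flagged / n_reps
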