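"""Independent brute-force oracles used by the test suite.

These re-derive the expected results from the rule definitions with plain
O(n^2) enumeration and explicit quantifiers, independently of the
package's scanning implementations.
"""

from __future__ import annotations

from brfscan.core_model import ORIENT_L, ORIENT_R, Breakpoint


def _key(bp: Breakpoint) -> tuple:
    return (bp.sample_id, bp.chrom, bp.pos, bp.orient or "", bp.junction_id)


def _greedy(candidates):
    """Accept candidate pairs nearest-first; each breakpoint used once."""
    candidates.sort(key=lambda c: (c[0], _key(c[1]), _key(c[2])))
    used, out = set(), []
    for d, a, b in candidates:
        if id(a) in used or id(b) in used:
            continue
        used.update((id(a), id(b)))
        out.append((a, b, d))
    return out


def brute_force_adjacency(breakpoints, threshold):
    """All-pairs re-derivation of adjacency classification.

    Returns a dict with pair multisets per class, each pair encoded as
    (sample, chrom, pos_a, orient_a, pos_b, orient_b, distance).
    """

    def ordered(a, b):
        if (a.pos, a.orient or "", a.junction_id) > (b.pos, b.orient or "", b.junction_id):
            a, b = b, a
        return a, b

    oriented = [bp for bp in breakpoints if bp.orient is not None]
    per_group: dict = {}
    for bp in oriented:
        per_group.setdefault((bp.sample_id, bp.chrom), []).append(bp)

    result = {"insertion_overlap": [], "gapped": [], "parallel": [], "groups": []}
    for (sample, chrom), bps in sorted(per_group.items()):
        # stage 1: every (R, L) coordinate-ordered pair within threshold
        cands = []
        for i in range(len(bps)):
            for j in range(i + 1, len(bps)):
                a, b = ordered(bps[i], bps[j])
                d = b.pos - a.pos
                if d <= threshold and a.orient == ORIENT_R and b.orient == ORIENT_L:
                    cands.append((d, a, b))
        matched = _greedy(cands)
        consumed = {id(bp) for a, b, _ in matched for bp in (a, b)}
        for a, b, d in matched:
            result["insertion_overlap"].append(
                (sample, chrom, a.pos, a.orient, b.pos, b.orient, d))
        rem = [bp for bp in bps if id(bp) not in consumed]

        # stage 2: gapped (L, R)
        cands = []
        for i in range(len(rem)):
            for j in range(i + 1, len(rem)):
                a, b = ordered(rem[i], rem[j])
                d = b.pos - a.pos
                if d <= threshold and a.orient == ORIENT_L and b.orient == ORIENT_R:
                    cands.append((d, a, b))
        for a, b, d in _greedy(cands):
            result["gapped"].append((sample, chrom, a.pos, a.orient, b.pos, b.orient, d))

        # stage 3: parallel — a pair is reported iff same orientation,
        # within threshold, and no same-orientation breakpoint sorts
        # strictly between the two (relational definition of consecutive
        # members of a single-linkage run)
        for orient in (ORIENT_L, ORIENT_R):
            mem = sorted((bp for bp in rem if bp.orient == orient), key=_key)
            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    a, b = mem[i], mem[j]
                    d = b.pos - a.pos
                    if d > threshold:
                        continue
                    between = [m for m in mem if _key(a) < _key(m) < _key(b)]
                    if between:
                        continue
                    result["parallel"].append(
                        (sample, chrom, a.pos, a.orient, b.pos, b.orient, d))
            # groups: connected components linking members within threshold
            parent = list(range(len(mem)))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i in range(len(mem)):
                for j in range(i + 1, len(mem)):
                    if mem[j].pos - mem[i].pos <= threshold:
                        parent[find(i)] = find(j)
            comps: dict = {}
            for i in range(len(mem)):
                comps.setdefault(find(i), []).append(mem[i])
            for comp in comps.values():
                if len(comp) >= 2:
                    result["groups"].append(
                        (sample, chrom, orient, tuple(bp.pos for bp in comp)))
    for k in result:
        result[k].sort()
    return result


def catalog_to_oracle_form(catalog):
    """Encode an AdjacencyCatalog the same way as the brute-force oracle."""
    out = {"insertion_overlap": [], "gapped": [], "parallel": [], "groups": []}
    for p in catalog.pairs:
        out[p.cls].append((
            p.bp_a.sample_id, p.bp_a.chrom, p.bp_a.pos, p.bp_a.orient,
            p.bp_b.pos, p.bp_b.orient, p.distance))
    for g in catalog.groups:
        out["groups"].append(
            (g.sample_id, g.chrom, g.orientation, tuple(bp.pos for bp in g.members)))
    for k in out:
        out[k].sort()
    return out


def brute_nearest_opposite(pair_orient, inner_pos, breakpoints, chrom, sample):
    """Linear-scan nearest opposite-orientation breakpoint on the segment
    side (right of an R/R pair, left of an L/L pair)."""
    opp = ORIENT_L if pair_orient == ORIENT_R else ORIENT_R
    best = None
    for bp in breakpoints:
        if bp.chrom != chrom or bp.sample_id != sample or bp.orient != opp:
            continue
        if pair_orient == ORIENT_R and bp.pos > inner_pos:
            d = bp.pos - inner_pos
        elif pair_orient == ORIENT_L and bp.pos < inner_pos:
            d = inner_pos - bp.pos
        else:
            continue
        if best is None or d < best:
            best = d
    return best
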