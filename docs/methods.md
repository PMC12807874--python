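# Methods

## Coordinate and orientation conventions

All coordinates are 1-based inclusive. A breakpoint's position is the
terminal retained base; its orientation token records on which side the
retained sequence lies: `L` (retained left, a copy-number down-transition
reading left to right) or `R` (retained right, an up-transition). We use
L/R rather than +/− deliberately: published catalogs disagree about which
sign means which, so BEDPE strand letters map to orientations through a
named dialect (`caller-default`: `+`→L, `-`→R) that every writer records
in its header. Breakend VCF needs no dialect because the ALT bracket
syntax is unambiguous. BEDPE's 0-based half-open coordinates are
converted at the boundary.

## Adjacency classification

Within each sample and chromosome, two breakpoints within a threshold
*T* (default 20,000 bp, the scale below which offsets are plausibly
resection rather than independent breakage) form an adjacency whose class
is the orientation pattern in coordinate order: (R,L) insertion/overlap,
(L,R) gapped, (R,R)/(L,L) parallel.

Classification enforces an exclusion ordering: insertion/overlap pairs
are matched first (greedily, nearest first, deterministic tie-breaks) and
both members removed, because insertion breakpoints all fall within *T*
but arise from a different process than gapped or parallel adjacency.
Gapped and parallel classification then run *independently* on the
survivors — a breakpoint may belong to one gapped pair and one parallel
group, and it is exactly this intersection that defines reciprocal
configurations (nested deletions, reciprocal foldbacks, mixed
translocations), which identify the two reciprocal ends of one ancestral
DSB.

Runs of ≥ 2 same-orientation breakpoints are grouped by single linkage
(transitive across gaps of exactly *T*; the alternative was not
specified anywhere authoritative, and single linkage matches the
grouping described for published catalogs); every consecutive pair in a
group is reported as a parallel pair. Pairs at distance 0 are kept and
flagged `flush`. When > 2 breakpoints cluster around an insertion, both
members of each matched insertion/overlap pair are removed.

A consequence worth stating: the *pair set* is not globally monotone in
*T*. Raising *T* can create a new insertion/overlap match that consumes
a breakpoint which previously formed a gapped or parallel pair. The
monotonicity property holds whenever exclusion cannot interfere (e.g.
single-orientation catalogs), and that is what the property tests
assert.

## Breakpoint independence

For a parallel pair at distance *d* derived from an ancestral segment of
length *L*, the probability that *k* additional independent breaks each
fall within *d* downstream of the first (one-sided window) is
p = (d/L)^k. In catalog mode *L* is unknown and is bounded below by the
distance from the pair's inner (segment-proximal) member to the nearest
surviving opposite-orientation breakpoint on the side the segment
extends — right of an R/R pair, left of an L/L pair. Inner-member
anchoring is our choice (the anchor was not specified); since the
estimate is a lower bound of *L*, p is an upper bound of the true
probability, which is the conservative direction for flagging. Pairs are
flagged non-independent when p < α (strict inequality, α = 0.05, no
multiple-testing correction by design). When no opposite breakpoint
exists the chromosome end is used and the pair is censored: reported,
excluded from flag counts.

Calibration: the Monte-Carlo null places one extra break uniformly on a
segment of *known* length, so p = d/L is uniform on [0, 1) and the
flagged fraction at α estimates α. We calibrate in known-length mode
because the estimated-length statistic is deliberately an upper bound
(anti-conservative L, conservative p) and is validated separately by the
upper-bound property test against simulator truth.

## Insertions, tiles, chains, strand concordance

Insertions come from explicit junction fragment annotations and, for
catalogs without them, from insertion/overlap pairs spanning at most the
insertion ceiling (default 10 kb for subclone-resolved analysis; catalog
scans share *T*). Origin tiling is detected by single linkage of origin
intervals within 10 kb; tiles need ≥ 4 members. Gap/overlap distances
are computed between coordinate-sorted members (not destination order);
"little gap or overlap" is operationalized as |gap| ≤ 50 bp, and origin
overlaps ≥ 10 bp are counted separately because they discriminate
template switching from gap-filling synthesis. A tile abutting a
breakpoint is annotated with the side and the origin strand implied by
the 3′-overhang rule (recorded as inferred; explicit strands are never
overwritten).

A chain is a junction with ≥ 2 insertions. Consecutive pairs with both
strands known are tallied as same- or opposite-strand; pairs involving
an unknown strand are skipped (counts are over known-strand pairs only).
Any opposite-strand pair excludes a conservative replicative origin
(MMBIR), since conservative synthesis appends every insertion to one
nascent strand.

## Strand signatures

Kataegis detection is a maximal-run scan: inter-mutation distance
≤ 2,000 bp, ≥ 3 members, 80% class purity — defaults we chose (the
source analyses reviewed clusters manually) and echo into output
headers. Cluster classes: `fwd_C` (C>T/G/A with 5′ T neighbour) and
`rev_C` (G>A/C/T with 3′ A neighbour), using per-substitution
trinucleotide context or a reference lookup. The offset interval of a
staggered pair is [inner, outer] inclusive; the geometry of 5′ resection
makes the exposed overhang reverse-strand on the left side of a
right-extending segment (expect `rev_C`) and forward-strand on the right
side of a left-extending segment (expect `fwd_C`). A cluster is
consistent when ≥ 90% of members lie inside the offset interval (the
containment fraction is our choice; "restricted to" was not quantified)
and its class matches the side rule. Clusters straddling the abutting
offsets of two reciprocal ends are intrinsically ambiguous and are
reported with both overlaps rather than forced to a verdict.

## Segment reconstruction

Four rules, applied verbatim and nothing more: (1) per-breakpoint copy
change across 25 kb bins, with a partner-breakpoint fallback when two
breakpoints share a bin; (2) retained regions flanked by deletions fix
segment boundaries directly; (3) segments propagate to subclones where
both boundary breakpoints recur (assumes no non-allelic homologous
recombination); (4) a multi-copy region flanked by parallel pairs on
both sides is phased into two sisters pairing outer-left with
inner-right — each sister joins one 3′-derived and one 5′-derived end,
never the two outer ends (that would exceed the ancestral fragment).
Flush sides are shared with unknown provenance. Conflicts between rules
are reported, not auto-resolved; full karyotype assembly is out of
scope.

## The simulator

One chromatid of a 50 Mb chromosome receives Poisson(50) uniformly
placed DSBs. Each end draws a resection length from a log-normal with
median 500 bp and σ = 1.175 (97.5th percentile ≈ 5 kb), hard-capped at
20 kb — chosen to bracket the printed example offsets of a few hundred
bp to ~2 kb; 15% of ends are flush (no offset). Each end independently
persists into S phase with probability 0.5, else ligates in G1 (random
pairing, ≤ 10 bp trimming, ≤ 2 bp microhomology, no insertions).
Replication turns every unligated end into a 3′-derived (full-length)
and a 5′-derived (recessed) sister end, with the strand bookkeeping
done per chromatid so that opposite ends of one sister segment carry
opposite polarities. Sister ends fold back on each other with
probability 0.3, otherwise enter a random fusion pool (15% stay
unligated and are lost). The assembled molecule graph is a union of
paths/cycles; the longest molecule (centromere proxy) is always
retained, other molecules with probability 0.5. Copy number is the
intact homolog (haplotype B) plus the coverage multiset of retained
sister segments (haplotype A, zero segments explicit).

Insertion chains are attached only to S/G2 fusion junctions: donor
overhangs ≥ 1 kb on catalog-visible ends (up to 3 donors) are tiled with
log-normal fragments (median 184 bp, σ = 0.6) separated by N(15, 15) bp
gaps with overlaps capped below 10 bp, plus a few scattered distal
fragments; fragments are dealt into chains of length 1 + Poisson(1.5)
with uniformly random destination strand (10% unknown). The MMBIR mode
instead draws 40 chains of single-strand insertions whose origins jump
20 kb–2 Mb between templates (re-invading within 10–150 bp of the
previous template 30% of the time, never twice in a row, so origin
clusters cannot reach tiling size); fresh invasions resample until they
land clear of previously used loci, which is what "scattered origins"
means operationally.

Deamination clusters (3 + Poisson(2) substitutions within a ≤ 1.5 kb
window) are planted in 60% of retained overhang offsets ≥ 50 bp with the
side-appropriate class, plus Poisson(60) random background substitutions
genome-wide. Amplification modes operate on a 0.5 Mb acentric fragment:
head-to-tail circle (episome I), double-foldback dimer circle
(episome II) with uneven binomial segregation, and the linear inverted
array, simulated by explicit molecule doubling so the copy profile,
foldback positions and edge staggering are exact (copy cap 256,
generations truncated with a warning).

What the generator does and does not emulate: it produces breakpoint
catalogs, copy profiles, substitutions and insertion tables with exact
truth, but no sequencing reads, no alignment artifacts, no caller error,
no repeats or mappability structure, and no selection. Passing tests
therefore demonstrate correctness of the detection logic under the
generative model, not robustness to real-world calling noise. An
optional `min_dsb_spacing` keeps breaks farther apart than the adjacency
threshold; the noise-free invariants (every planted sister pair
recovered, every G1 ligation a gapped pair) are asserted under that
condition, since chance co-location of independent breaks within the
threshold is precisely what the independence statistic exists to
quantify.

## Numerical choices and determinism

All randomness flows through one `numpy` Generator seeded from the
config; identical config + seed gives byte-identical output files. Ties
in greedy matching break on (distance, sample, chromosome, position,
junction id). Breakpoints at equal positions order L before R. Problem
sizes used by the default validation runs — Poisson(50) breaks, 10^4
calibration replicates, five-seed pools for the mechanism contrasts —
keep each run in seconds while leaving the Monte-Carlo bands (3 standard
errors) tight enough to be informative.

## Known limitations

- The nearest-opposite segment-length bound can exceed the true
  ancestral fragment when the flanking DNA was lost from the clone
  (no opposite breakpoint was emitted); the upper-bound property is
  therefore only guaranteed, and only asserted, where an opposite
  breakpoint within the fragment exists.
- Reciprocal-configuration typing requires junction topology; with
  catalog-only input (no junction back-references) configurations fall
  back to the mixed/translocation label.
- The reconstruction module implements the four stated rules only;
  regions they cannot resolve are labeled, not assembled.
- Insertion candidates from (R,L) adjacency conflate true templated
  insertions with replication-bypass overlaps, mirroring the upstream
  decision not to distinguish them.
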