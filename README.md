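# brfscan

Detection, statistics and simulation of **breakage–replication/fusion**
rearrangement signatures in structural-variant catalogs.

## The problem

A replisome passing through an unrepaired double-strand-break (DSB) end
copies that end into two non-identical "sister" ends: resection of the
5′ strand before replication leaves the two sister breakpoints offset by
the resection length. Fusions of these replicated ends leave a
recognizable set of genomic footprints:

- **adjacent parallel breakpoints** — two nearby breakpoints with the
  *same* orientation (both copy-number up-transitions or both
  down-transitions), derived from one ancestral DNA end;
- **foldback junctions** — direct ligation of the two sister ends
  (intrachromosomal, same-orientation, short-distance junctions);
- **chains of short insertions** at fusion junctions whose origins tile
  single-stranded overhang regions, incorporated in *random* orientation
  (unlike the strictly one-stranded chains predicted by
  microhomology-mediated break-induced replication, MMBIR);
- **strand-coordinated kataegis** (TpC-context deamination) confined to
  the offset interval between staggered breakpoints — the exposed 3′
  overhang;
- **inverted segmental amplification**: sister-end fusion on one side of
  an acentric fragment doubles it each generation, so after *g*
  generations the amplicon sits at 2^g copies bounded by clustered
  foldbacks.

`brfscan` classifies breakpoint adjacency in junction catalogs (BEDPE or
breakend VCF), scores whether parallel pairs could have arisen from
independent breaks, extracts insertion chains and origin tiles, tests the
overhang deamination rule, reconstructs duplicated sister segments from
subclonal copy number, and ships a mechanistic simulator that generates
all of these signatures with a ground-truth sidecar.

## The statistics at the core

Adjacency classification uses a heuristic threshold *T* = 20 kb.
Insertion/overlap pairs (orientation pattern R,L in coordinate order) are
excluded first; gapped (L,R) and parallel (R,R / L,L) pairs are then
classified on the survivors, with same-orientation runs grouped by single
linkage.

For a parallel pair at distance *d* on an ancestral segment of length
*L*, the probability that *k* additional independent breaks all fall
within *d* of the first is

    p = (d / L)^k

For example, two extra breaks within 10 kb on a 0.5 Mb segment give
(10 kb / 0.5 Mb)² = 0.0004. When *L* is unknown it is bounded below by
the distance to the nearest opposite-orientation breakpoint, making *p*
an upper bound; pairs with *p* < 0.05 are flagged as non-independent,
i.e. as candidate sister ends.

## Worked example

```sh
brf-sim --seed 1 --out-dir sim/
brf-scan scan --junctions sim/junctions.bedpe --cn sim/cn.bed \
    --substitutions sim/substitutions.vcf --out scan/
```

or equivalently in Python:

```python
from brfscan import SimConfig, simulate, run_scan, evaluate_detection

out = simulate(SimConfig(seed=1))          # ~50 DSBs on a 50 Mb chromosome
res = run_scan(out.junctions, out.cn_profile, out.substitutions)
print(res.report["pairs_by_class"])
print(res.report["independence"]["statement"])
print(evaluate_detection(res, out.truth).to_string(index=False))
```

which prints:

```
{'insertion_overlap': 1, 'gapped': 46, 'parallel': 30, 'parallel_groups': 30, 'breakpoints': 120}
30 of 30 pairs of adjacent parallel breakpoints have independence probability < 0.05
            signature  tp  fp  fn  precision  recall  f1
sister_parallel_pairs  30   0   0        1.0     1.0 1.0
            foldbacks   7   0   0        1.0     1.0 1.0
                tiles   3   0   0        1.0     1.0 1.0
               chains   9   0   0        1.0     1.0 1.0
```

Reading this: of 120 breakpoints in the simulated catalog, 30 pairs of
adjacent parallel breakpoints were found, every one with an independence
probability below 5% — the statistical signature of sister DNA ends —
and comparison against the simulator's truth sidecar shows that all 30
are exactly the planted sister pairs (precision = recall = 1), along
with all planted foldbacks, insertion-origin tiles and insertion chains.

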