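"""Scan orchestration, reports and truth-based evaluation.

``run_scan`` executes the detection stages in mechanism order —
adjacency classification, breakpoint-independence scoring, insertion
extraction (tiles, chains, strand concordance), clustered-substitution
strand signatures — and labels breakpoint runs with orientation-motif
footprints.  Missing optional inputs degrade gracefully: the
corresponding stages are skipped and noted in the report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import adjacency as adj
from . import independence as indep
from . import insertions as ins_mod
from . import strand_signatures as sigs
from .core_model import (
    CopyNumberProfile,
    Junction,
    Substitution,
    orient_from_copy_number,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class ScanConfig:
    threshold: int = adj.DEFAULT_THRESHOLD
    insertion_max_span: int = ins_mod.DEFAULT_MAX_SPAN
    alpha: float = indep.DEFAULT_ALPHA
    k: int = 1
    max_gap: int = sigs.DEFAULT_MAX_GAP
    min_cluster_size: int = sigs.DEFAULT_MIN_SIZE
    tile_window: int = ins_mod.DEFAULT_TILE_WINDOW
    min_tile_members: int = ins_mod.DEFAULT_MIN_MEMBERS
    chrom_bounds: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanResult:
    report: dict
    catalog: adj.AdjacencyCatalog
    scores: list[indep.PairScore]
    insertions: list
    tiles: list
    chains: list
    concordance: dict
    clusters: list
    consistency: list[dict]
    reciprocal: list
    foldbacks: list
    footprints: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        """Flat TSV-ready views of the scan results."""
        pair_rows = []
        score_by_key = {s.pair.key: s for s in self.scores}
        for p in self.catalog.pairs:
            s = score_by_key.get(p.key)
            pair_rows.append({
                "class": p.cls, "chrom": p.bp_a.chrom,
                "pos_a": p.bp_a.pos, "pos_b": p.bp_b.pos,
                "orient_a": p.bp_a.orient, "orient_b": p.bp_b.orient,
                "distance": p.distance, "flush": p.flush, "group_id": p.group_id,
                "L": s.L if s else None, "L_source": s.L_source if s else None,
                "r": s.r if s else None, "p_indep": s.p_indep if s else None,
                "non_independent": s.non_independent if s else None,
            })
        ins_rows = [{
            "junction_id": i.dest_junction_id, "index_in_chain": i.index_in_chain,
            "origin_chrom": i.origin_chrom, "origin_start": i.origin_start,
            "origin_end": i.origin_end, "strand": i.origin_strand, "length": i.length,
            "nearest_bp_distance": i.nearest_ancestral_bp[0] if i.nearest_ancestral_bp else None,
        } for i in self.insertions]
        tile_rows = [{
            "chrom": t.chrom, "start": t.start, "end": t.end,
            "n_members": len(t.members), "frac_small_gap": t.frac_small_gap,
            "frac_overlap": t.frac_overlap, "inferred_strand": t.inferred_strand,
        } for t in self.tiles]
        chain_rows = [{
            "junction_id": c.junction_id, "n_insertions": len(c.insertions),
            "pattern": c.strand_pattern, "same": c.same_strand_pairs,
            "opposite": c.opposite_strand_pairs,
        } for c in self.chains]
        return {
            "pairs": pd.DataFrame(pair_rows),
            "insertions": pd.DataFrame(ins_rows),
            "tiles": pd.DataFrame(tile_rows),
            "chains": pd.DataFrame(chain_rows),
            "signatures": pd.DataFrame(self.consistency),
        }


def _footprint_motifs(catalog: adj.AdjacencyCatalog, threshold: int) -> dict:
    """Orientation words of maximal breakpoint runs (consecutive surviving
    breakpoints within the threshold).  Three- and five-breakpoint words
    containing a parallel pair next to an opposite-orientation breakpoint
    are the footprints explainable by one breakage-replication/fusion
    cycle."""
    runs: dict[str, int] = {}
    by_group: dict[tuple[str, str], list] = {}
    for bp in catalog.surviving:
        by_group.setdefault((bp.sample_id, bp.chrom), []).append(bp)
    for (_, _), bps in sorted(by_group.items()):
        bps.sort(key=lambda b: (b.pos, b.orient or ""))
        run = []
        for bp in bps + [None]:
            if bp is not None and (not run or bp.pos - run[-1].pos <= threshold):
                run.append(bp)
                continue
            if len(run) >= 3:
                word = "".join(b.orient for b in run)
                runs[word] = runs.get(word, 0) + 1
            run = [bp] if bp is not None else []
    def has_parallel_adjacent(word: str) -> bool:
        return any(a == b for a, b in zip(word, word[1:])) and len(set(word)) == 2
    return {
        "words": runs,
        "three_breakpoint": {w: c for w, c in runs.items() if len(w) == 3 and has_parallel_adjacent(w)},
        "five_breakpoint": {w: c for w, c in runs.items() if len(w) == 5 and has_parallel_adjacent(w)},
    }


def run_scan(
    junctions: Sequence[Junction],
    cn_profile: CopyNumberProfile | None = None,
    substitutions: Sequence[Substitution] | None = None,
    reference=None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """Run the full detection pipeline over a junction catalog."""
    config = config or ScanConfig()
    skipped = []
    breakpoints = [bp for j in junctions for bp in j.breakpoints]
    if cn_profile is not None and any(bp.orient is None for bp in breakpoints):
        breakpoints, _ = orient_from_copy_number(breakpoints, cn_profile)

    catalog = adj.classify_adjacency(breakpoints, config.threshold)
    foldbacks = adj.detect_foldbacks(junctions, config.threshold)
    reciprocal = adj.find_reciprocal(catalog, junctions)
    scores, indep_summary = indep.flag_non_independent(
        catalog, config.alpha, config.k, config.chrom_bounds or None
    )

    insertions = ins_mod.extract_insertions(
        junctions, catalog, max_span=config.insertion_max_span
    )
    tiles = ins_mod.detect_tiles(
        insertions, config.tile_window, config.min_tile_members,
        breakpoints=catalog.surviving,
    )
    chains = ins_mod.assemble_chains(junctions)
    concordance = ins_mod.strand_concordance(chains)

    clusters: list = []
    consistency: list[dict] = []
    if substitutions:
        clusters = sigs.detect_clusters(substitutions, config.max_gap, config.min_cluster_size)
        staggered = catalog.pairs_of(adj.CLASS_PARALLEL)
        consistency = sigs.offset_consistency(clusters, staggered, reference)
    else:
        skipped.append("strand_signatures (no substitutions provided)")

    footprints = _footprint_motifs(catalog, config.threshold)

    mapped = [i for i in insertions if i.has_origin]
    sizes = sorted(i.length for i in mapped)
    near = sum(1 for i in mapped if i.nearest_ancestral_bp is not None)
    n_bps = len([bp for bp in breakpoints if bp.orient is not None])
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "n_junctions": len(junctions),
        "n_breakpoints": n_bps,
        "n_unoriented": catalog.skipped_unoriented,
        "pairs_by_class": dict(catalog.counts),
        "parallel_groups": len(catalog.groups),
        "foldbacks": len(foldbacks),
        "reciprocal": {
            kind: sum(1 for r in reciprocal if r.kind == kind and not r.partial)
            for kind in (adj.KIND_NESTED_DELETIONS, adj.KIND_RECIPROCAL_FOLDBACKS,
                         adj.KIND_MIXED_TRANSLOCATION)
        },
        "reciprocal_partial": sum(1 for r in reciprocal if r.partial),
        "independence": indep_summary,
        "insertions": {
            "count": len(insertions),
            "mapped": len(mapped),
            "median_size": float(sizes[len(sizes) // 2]) if sizes else None,
            "fraction_near_breakpoint": near / len(mapped) if mapped else None,
            "fraction_of_breakpoints": (
                2 * len(insertions) / n_bps if n_bps else None
            ),
        },
        "chains": {"count": len(chains), "concordance": {
            k: v for k, v in concordance.items() if k != "chains"}},
        "tiles": {"count": len(tiles)},
        "clusters": {"count": len(clusters),
                     "consistent": sum(1 for row in consistency if row["consistent"]),
                     "tested": len(consistency)},
        "footprints": footprints,
        "stages_skipped": skipped,
    }
    return ScanResult(report, catalog, scores, insertions, tiles, chains,
                      concordance, clusters, consistency, reciprocal, foldbacks,
                      footprints)


# ---------------------------------------------------------------------------
# evaluation against simulator truth
# ---------------------------------------------------------------------------


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision and recall and precision + recall
        else (0.0 if precision is not None and recall is not None else None)
    )
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def evaluate_detection(result: ScanResult, truth: Mapping) -> pd.DataFrame:
    """Per-signature precision/recall of a scan against the simulator's
    truth sidecar (matching by breakpoint identity)."""
    rows = []

    detected_pairs = {
        (p.bp_a.chrom, p.bp_a.pos, p.bp_b.pos, p.bp_a.orient)
        for p in result.catalog.pairs_of(adj.CLASS_PARALLEL)
    }
    truth_pairs = {
        (t["chrom"], t["pos_a"], t["pos_b"], t["orient"])
        for t in truth.get("sister_pairs", ())
    }
    tp = len(detected_pairs & truth_pairs)
    rows.append({"signature": "sister_parallel_pairs",
                 **_prf(tp, len(detected_pairs - truth_pairs), len(truth_pairs - detected_pairs))})

    detected_fb = {j.id for j, _, _ in result.foldbacks}
    truth_fb = set(truth.get("foldback_junction_ids", ()))
    tp = len(detected_fb & truth_fb)
    rows.append({"signature": "foldbacks",
                 **_prf(tp, len(detected_fb - truth_fb), len(truth_fb - detected_fb))})

    truth_tiles = truth.get("tiles", ())
    matched_truth = set()
    fp_tiles = 0
    for tile in result.tiles:
        hit = None
        for i, t in enumerate(truth_tiles):
            if tile.start <= t["end"] and t["start"] <= tile.end:
                hit = i
                break
        if hit is None:
            fp_tiles += 1
        else:
            matched_truth.add(hit)
    rows.append({"signature": "tiles",
                 **_prf(len(matched_truth), fp_tiles, len(truth_tiles) - len(matched_truth))})

    detected_chains = {c.junction_id for c in result.chains}
    truth_chains = {t["junction_id"] for t in truth.get("chains", ())}
    tp = len(detected_chains & truth_chains)
    rows.append({"signature": "chains",
                 **_prf(tp, len(detected_chains - truth_chains), len(truth_chains - detected_chains))})

    return pd.DataFrame(rows)
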