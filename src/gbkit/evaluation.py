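"""Scoring of inferred painted karyotypes against simulation ground truth."""

from __future__ import annotations

from .adjacency import extract_adjacencies
from .gb_projection import GBMap

__all__ = ["map_boundaries", "boundary_recovery", "adjacency_recovery", "inversion_flag_agreement"]


def map_boundaries(gb_map: GBMap) -> set[tuple[str, int]]:
    """All sub-block boundary positions of a map as (chrom, gene rank)."""
    out: set[tuple[str, int]] = set()
    for chrom, subs in gb_map.chromosomes.items():
        for sb in subs:
            out.add((chrom, sb.rank_start))
            out.add((chrom, sb.rank_end))
    return out


def boundary_recovery(true_map: GBMap, inferred_map: GBMap, tol: int = 25) -> float:
    """Fraction of true sub-block boundaries with an inferred boundary on the
    same chromosome within ``tol`` gene ranks."""
    truth = map_boundaries(true_map)
    inferred = map_boundaries(inferred_map)
    if not truth:
        return 1.0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in inferred:
        by_chrom.setdefault(chrom, []).append(pos)
    hit = sum(
        1
        for chrom, pos in truth
        if any(abs(pos - q) <= tol for q in by_chrom.get(chrom, ()))
    )
    return hit / len(truth)


def adjacency_recovery(true_map: GBMap, inferred_map: GBMap, max_gap_genes: int = 50) -> float:
    """Fraction of true adjacencies present in the inferred map."""
    truth = extract_adjacencies(true_map, max_gap_genes)
    if not truth:
        return 1.0
    found = extract_adjacencies(inferred_map, max_gap_genes)
    return len(truth & found) / len(truth)


def inversion_flag_agreement(true_map: GBMap, inferred_map: GBMap) -> tuple[int, int]:
    """Match inferred sub-blocks to overlapping true sub-blocks of the same
    GB label and count inversion-flag agreement.  Returns (matched, agreeing)."""
    matched = agree = 0
    for chrom, subs in inferred_map.chromosomes.items():
        truth = true_map.chromosomes.get(chrom, [])
        for sb in subs:
            best = None
            best_ov = 0
            for tb in truth:
                if tb.gb_label != sb.gb_label:
                    continue
                ov = min(sb.rank_end, tb.rank_end) - max(sb.rank_start, tb.rank_start) + 1
                if ov > best_ov:
                    best, best_ov = tb, ov
            if best is None:
                continue
            matched += 1
            if best.inverted == sb.inverted:
                agree += 1
    return matched, agree
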