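"""Projection of ortholog syntenic blocks onto the ancestral genomic blocks.

Each retained ortholog block is split at every genomic-block (GB) interval
boundary its reference span crosses; the resulting fragments become
GB-lettered sub-blocks of the query genome's painted karyotype.  Fragments
of one GB are numbered 1..k by the order of their start positions on the
ancestral reference ("ordered relative to the ACK"), and a fragment is
flagged inverted when its anchors run antiparallel to the reference
direction of its GB (majority orientation = sign of the Spearman rank
correlation between query and reference anchor ranks; |rho| < 0.5 is
reported ambiguous and not inverted).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from scipy.stats import spearmanr

from .chaining import Origin, SyntenicBlock
from .io_formats import GBDefinition, GenomeAnnotation

log = logging.getLogger(__name__)

__all__ = ["SubBlock", "GBMap", "project_block", "build_gb_map", "DEFAULT_ALLOW_SMALL"]

DEFAULT_ALLOW_SMALL = frozenset({"G"})

UNASSIGNED = "unassigned"


@dataclass
class SubBlock:
    """A fragment of one genomic block on a query chromosome."""

    gb_label: str
    index: int  # 1-based position of this fragment within its GB, ACK order
    chrom: str  # query chromosome
    rank_start: int  # inclusive query rank span
    rank_end: int
    bp_start: int
    bp_end: int
    inverted: bool
    ambiguous: bool
    n_genes: int  # anchors supporting the fragment
    ref_chrom: str
    ref_start: int  # inclusive reference rank span
    ref_end: int
    block_id: str = ""
    # supporting anchors; carried through map construction, not serialised
    members: list | None = field(default=None, compare=False, repr=False)


@dataclass
class GBMap:
    """A painted karyotype: per-chromosome ordered lists of sub-blocks."""

    genome_id: str
    chromosomes: dict[str, list[SubBlock]]

    def sub_blocks(self):
        for subs in self.chromosomes.values():
            yield from subs

    @property
    def n_sub_blocks(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())


def _interval_index(gb_table: list[GBDefinition]):
    by_chrom: dict[str, list[tuple[int, int, GBDefinition]]] = {}
    for d in gb_table:
        by_chrom.setdefault(d.ref_chrom, []).append((d.rank_start, d.rank_end, d))
    for ivs in by_chrom.values():
        ivs.sort()
    return by_chrom


def _lookup(by_chrom, chrom: str, rank: int) -> GBDefinition | None:
    ivs = by_chrom.get(chrom)
    if not ivs:
        return None
    i = bisect.bisect_right(ivs, (rank, float("inf"), None)) - 1
    if i >= 0 and ivs[i][0] <= rank <= ivs[i][1]:
        return ivs[i][2]
    return None


def _fragment_orientation(anchors, block: SyntenicBlock) -> tuple[int, bool]:
    """Majority orientation of a fragment's anchors.

    Returns (sign, ambiguous).  Single-anchor fragments fall back to the
    block orientation.  Within one chained block anchors are globally
    monotone so |rho| is 1 in practice; the ambiguity path guards manually
    merged or externally constructed blocks.
    """
    if len(anchors) < 2:
        return block.orientation, True
    rho = spearmanr([a.rank_a for a in anchors], [a.rank_b for a in anchors]).statistic
    if abs(rho) < 0.5:
        return block.orientation, True
    return (1 if rho > 0 else -1), False


def project_block(
    block: SyntenicBlock,
    gb_table: list[GBDefinition],
    min_subblock: int = 20,
    allow_small: frozenset[str] = DEFAULT_ALLOW_SMALL,
) -> list[SubBlock]:
    """Split one ortholog block at every GB boundary it crosses.

    Fragments supported by fewer than ``min_subblock`` anchors are dropped
    unless their GB label is in ``allow_small`` (the block-G exception: a
    six-gene block that is real but below the global threshold).  Anchors
    whose reference rank falls outside every GB interval form fragments
    labeled "unassigned".
    """
    if block.origin != Origin.ORTHOLOG:
        raise ValueError(
            f"block {block.block_id} has origin {block.origin}; only ORTHOLOG "
            "blocks are projected"
        )
    by_chrom = _interval_index(gb_table)
    ordered = sorted(block.anchors, key=lambda pa: pa.rank_b)
    runs: list[tuple[GBDefinition | None, list]] = []
    for pa in ordered:
        gb = _lookup(by_chrom, block.chrom_b, pa.rank_b)
        if runs and runs[-1][0] is gb:
            runs[-1][1].append(pa)
        else:
            runs.append((gb, [pa]))
    fragments: list[SubBlock] = []
    for gb, members in runs:
        label = gb.label if gb is not None else UNASSIGNED
        if gb is None:
            log.info(
                "block %s: %d anchors outside every GB interval (unassigned)",
                block.block_id,
                len(members),
            )
        if len(members) < min_subblock and label not in allow_small:
            log.debug(
                "block %s: dropped %d-anchor fragment in GB %s (< %d)",
                block.block_id,
                len(members),
                label,
                min_subblock,
            )
            continue
        sign, ambiguous = _fragment_orientation(members, block)
        direction = gb.direction if gb is not None else 1
        ranks_a = [pa.rank_a for pa in members]
        ranks_b = [pa.rank_b for pa in members]
        fragments.append(
            SubBlock(
                gb_label=label,
                index=0,  # assigned by build_gb_map
                chrom=block.chrom_a,
                rank_start=min(ranks_a),
                rank_end=max(ranks_a),
                bp_start=-1,
                bp_end=-1,
                inverted=(not ambiguous) and sign * direction < 0,
                ambiguous=ambiguous,
                n_genes=len(members),
                ref_chrom=block.chrom_b,
                ref_start=min(ranks_b),
                ref_end=max(ranks_b),
                block_id=block.block_id,
                members=list(members),
            )
        )
    return fragments


def _remake(f: SubBlock, members: list) -> SubBlock:
    """Rebuild a fragment from a subset of its anchors (orientation flags
    are inherited: a contiguous sub-run of a monotone run keeps its sense)."""
    ranks_a = [pa.rank_a for pa in members]
    ranks_b = [pa.rank_b for pa in members]
    return SubBlock(
        gb_label=f.gb_label,
        index=0,
        chrom=f.chrom,
        rank_start=min(ranks_a),
        rank_end=max(ranks_a),
        bp_start=-1,
        bp_end=-1,
        inverted=f.inverted,
        ambiguous=f.ambiguous,
        n_genes=len(members),
        ref_chrom=f.ref_chrom,
        ref_start=min(ranks_b),
        ref_end=max(ranks_b),
        block_id=f.block_id,
        members=list(members),
    )


def _resolve_query_overlaps(
    fragments: list[SubBlock], min_subblock: int, allow_small: frozenset[str]
) -> list[SubBlock]:
    """Give every query gene to at most one fragment and make sub-block
    spans non-overlapping.

    Phase 1 admits fragments largest-first with per-gene exclusivity: an
    anchor whose query gene is already claimed by an admitted fragment is
    trimmed away (one-to-many homologs resolve to the larger fragment).

    Phase 2 splits every fragment wherever another fragment's anchors fall
    between its consecutive anchors -- a chain that legally jumped a gap
    containing a foreign insertion is cut at the insertion rather than
    masking it.  Pieces must still meet the sub-block size floor.
    """
    order = sorted(
        fragments, key=lambda f: (-f.n_genes, f.chrom, f.rank_start, f.gb_label, f.block_id)
    )
    taken: dict[str, set[int]] = {}
    admitted: list[tuple[SubBlock, list]] = []
    for f in order:
        claimed = taken.setdefault(f.chrom, set())
        members = sorted(
            (pa for pa in (f.members or []) if pa.rank_a not in claimed),
            key=lambda pa: pa.rank_a,
        )
        if len(members) < len(f.members or []):
            log.info(
                "overlap on %s: trimmed %d shared genes from %s fragment",
                f.chrom,
                len(f.members or []) - len(members),
                f.gb_label,
            )
        if not members:
            continue
        claimed.update(pa.rank_a for pa in members)
        admitted.append((f, members))
    # Stepping-stone removal: when the spans of two admitted fragments
    # overlap and both have anchors in the shared interval, the fragment
    # with fewer anchors there forfeits them.  This strips the stray
    # anchors a chain picks up while bridging across a rearranged segment
    # (e.g. one forward anchor inside an inversion) without letting them
    # shatter the genuine fragment underneath.
    work = [[f, members] for f, members in admitted]
    for _ in range(5):
        changed = False
        for i in range(len(work)):
            fi, mi = work[i]
            if not mi:
                continue
            for j in range(i + 1, len(work)):
                fj, mj = work[j]
                if not mj or fi.chrom != fj.chrom:
                    continue
                lo = max(mi[0].rank_a, mj[0].rank_a)
                hi = min(mi[-1].rank_a, mj[-1].rank_a)
                if lo > hi:
                    continue
                ins_i = [pa for pa in mi if lo <= pa.rank_a <= hi]
                ins_j = [pa for pa in mj if lo <= pa.rank_a <= hi]
                if not ins_i or not ins_j:
                    continue
                loser = i if (len(ins_i), len(mi)) < (len(ins_j), len(mj)) else j
                drop = {id(pa) for pa in (ins_i if loser == i else ins_j)}
                work[loser][1] = [pa for pa in work[loser][1] if id(pa) not in drop]
                log.info(
                    "overlap on %s: removed %d bridging anchors from %s fragment",
                    fi.chrom,
                    len(drop),
                    work[loser][0].gb_label,
                )
                changed = True
        if not changed:
            break
    admitted = [(f, members) for f, members in work if members]

    # split at remaining foreign anchors, then apply the size floor
    occupancy: dict[str, list[tuple[int, int]]] = {}
    for fid, (f, members) in enumerate(admitted):
        occupancy.setdefault(f.chrom, []).extend((pa.rank_a, fid) for pa in members)
    for ranks in occupancy.values():
        ranks.sort()
    kept: list[SubBlock] = []
    for fid, (f, members) in enumerate(admitted):
        ranks = occupancy[f.chrom]
        groups: list[list] = [[members[0]]]
        for prev, cur in zip(members, members[1:]):
            lo = bisect.bisect_right(ranks, (prev.rank_a, 1 << 30))
            hi = bisect.bisect_left(ranks, (cur.rank_a, -1))
            if any(ranks[i][1] != fid for i in range(lo, hi)):
                groups.append([cur])
            else:
                groups[-1].append(cur)
        for grp in groups:
            if len(grp) < min_subblock and f.gb_label not in allow_small:
                continue
            kept.append(_remake(f, grp))
    return kept


def assign_indices(fragments: list[SubBlock]) -> None:
    """Number fragments of each GB 1..k by ancestral (reference) start order."""
    by_label: dict[str, list[SubBlock]] = {}
    for f in fragments:
        by_label.setdefault(f.gb_label, []).append(f)
    for label, frs in by_label.items():
        frs.sort(key=lambda f: (f.ref_chrom, f.ref_start, f.chrom, f.rank_start))
        for i, f in enumerate(frs, start=1):
            f.index = i


def build_gb_map(
    blocks,
    gb_table: list[GBDefinition],
    ann_query: GenomeAnnotation,
    min_subblock: int = 20,
    allow_small: frozenset[str] = DEFAULT_ALLOW_SMALL,
) -> GBMap:
    """Paint the query karyotype from its classified syntenic blocks.

    Only ORTHOLOG blocks contribute.  Overlapping fragments on the query
    are resolved by keeping the larger fragment (conflict logged); surviving
    fragments of each GB are numbered in ancestral order and sorted per
    query chromosome.
    """
    fragments: list[SubBlock] = []
    for b in blocks:
        if b.origin != Origin.ORTHOLOG:
            continue
        fragments.extend(project_block(b, gb_table, min_subblock, allow_small))
    kept = _resolve_query_overlaps(fragments, min_subblock, allow_small)
    assign_indices(kept)
    chrom_map: dict[str, list[SubBlock]] = {}
    for chrom_id, chrom in ann_query.chromosomes.items():
        subs = sorted(
            (f for f in kept if f.chrom == chrom_id), key=lambda f: f.rank_start
        )
        for f in subs:
            f.bp_start = chrom.genes[f.rank_start].start
            f.bp_end = chrom.genes[f.rank_end].end
        if subs:
            chrom_map[chrom_id] = subs
    return GBMap(ann_query.genome_id, chrom_map)
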