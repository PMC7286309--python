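"""Collinearity chaining of anchor pairs into oriented syntenic blocks.

The chainer works in gene-rank space, DAGchainer-style: anchors are points
(rank_a, rank_b); a chain is a run of anchors strictly increasing in rank_a
and strictly monotone in rank_b, with consecutive anchors at most ``max_gap``
ranks apart in both genomes.  Chains are scored as

    sum of anchor scores  -  gap_penalty * sum of gap lengths,

where the gap length between consecutive anchors is max(d_a, d_b) - 1
skipped ranks.  Extraction is greedy best-first: the maximum-score chain is
found by dynamic programming, its anchors are removed, and the search
repeats, so every anchor ends up in at most one block.  Antisense chains are
found by negating rank_b and re-running the same DP.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from statistics import mean, median

from .io_formats import AnchorPair, GenomeAnnotation

log = logging.getLogger(__name__)

__all__ = [
    "Origin",
    "PlacedAnchor",
    "SyntenicBlock",
    "chain_anchors",
    "best_chain",
    "merge_blocks",
    "manual_merge",
]


class Origin:
    """Block origin classes (plain strings for easy serialisation)."""

    ORTHOLOG = "ORTHOLOG"
    WGD_PARALOG = "WGD_PARALOG"
    UNCLASSIFIED = "UNCLASSIFIED"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class PlacedAnchor:
    """An anchor pair resolved to rank coordinates on its chromosome pair."""

    rank_a: int
    rank_b: int
    pair: AnchorPair


@dataclass
class SyntenicBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[PlacedAnchor]  # sorted by rank_a
    orientation: int  # +1 or -1
    median_ks: float | None = None
    mean_ks: float | None = None
    origin: str = Origin.UNCLASSIFIED
    note: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        return (self.anchors[0].rank_a, self.anchors[-1].rank_a)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return (min(ranks), max(ranks))

    def validate(self, max_gap: int | None = None) -> None:
        """Raise if the anchors are not a strictly monotone, gap-feasible run."""
        for prev, cur in zip(self.anchors, self.anchors[1:]):
            da = cur.rank_a - prev.rank_a
            db = (cur.rank_b - prev.rank_b) * self.orientation
            if da < 1 or db < 1:
                raise ValueError(
                    f"block {self.block_id}: anchors not strictly monotone "
                    f"with orientation {self.orientation:+d}"
                )
            if max_gap is not None and (da > max_gap or db > max_gap):
                raise ValueError(f"block {self.block_id}: gap exceeds {max_gap}")


# ---------------------------------------------------------------------------
# dynamic-programming chain extraction


def best_chain(
    points: list[tuple[int, int]],
    max_gap: int,
    gap_penalty: float,
    scores: list[float] | None = None,
) -> tuple[float, list[int]]:
    """Maximum-score chain over oriented points (strictly increasing in both
    coordinates, consecutive steps <= max_gap in both).

    Returns (score, indices into ``points``).  Ties between equal-score
    chains are broken by the lexicographically smallest chain start, then
    end.  Empty input returns (0.0, []).
    """
    n = len(points)
    if n == 0:
        return 0.0, []
    if scores is None:
        scores = [1.0] * n
    order = sorted(range(n), key=lambda i: points[i])
    ra = [points[order[i]][0] for i in range(n)]
    rb = [points[order[i]][1] for i in range(n)]
    sc = [scores[order[i]] for i in range(n)]
    dp = list(sc)
    pred = [-1] * n
    start = list(range(n))  # index (in sorted order) of the chain start
    eps = 1e-9
    for i in range(n):
        lo = bisect.bisect_left(ra, ra[i] - max_gap)
        for j in range(lo, i):
            da = ra[i] - ra[j]
            if da < 1:
                continue
            db = rb[i] - rb[j]
            if db < 1 or db > max_gap:
                continue
            cand = dp[j] + sc[i] - gap_penalty * (max(da, db) - 1)
            cur = dp[i]
            if cand > cur + eps or (
                abs(cand - cur) <= eps
                and pred[i] >= 0
                and (ra[start[j]], rb[start[j]]) < (ra[start[pred[i]]], rb[start[pred[i]]])
            ):
                dp[i] = cand
                pred[i] = j
                start[i] = start[j]
    best_i = 0
    for i in range(1, n):
        if dp[i] > dp[best_i] + eps:
            best_i = i
        elif abs(dp[i] - dp[best_i]) <= eps:
            key_i = (ra[start[i]], rb[start[i]], ra[i], rb[i])
            key_b = (ra[start[best_i]], rb[start[best_i]], ra[best_i], rb[best_i])
            if key_i < key_b:
                best_i = i
    chain: list[int] = []
    i = best_i
    while i != -1:
        chain.append(order[i])
        i = pred[i]
    chain.reverse()
    return dp[best_i], chain


def _resolve(anchors, ann_a: GenomeAnnotation, ann_b: GenomeAnnotation):
    groups: dict[tuple[str, str], list[PlacedAnchor]] = {}
    for p in anchors:
        ga, gb = ann_a.gene(p.gene_a), ann_b.gene(p.gene_b)
        groups.setdefault((ga.chrom, gb.chrom), []).append(
            PlacedAnchor(ga.rank, gb.rank, p)
        )
    return groups


def chain_anchors(
    anchors,
    ann_a: GenomeAnnotation,
    ann_b: GenomeAnnotation,
    max_gap: int = 25,
    min_pairs: int = 20,
    gap_penalty: float = 0.2,
    use_anchor_scores: bool = False,
) -> list[SyntenicBlock]:
    """Chain anchors into oriented collinear blocks.

    Defaults mirror SynMap practice for genomic-block detection: a maximum
    gap of 25 gene ranks between matches and a floor of 20 retained pairs
    per block.  Chain extraction itself is independent of ``min_pairs``
    (the floor filters afterwards), so raising the floor can only remove
    blocks.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    blocks: list[SyntenicBlock] = []
    groups = _resolve(anchors, ann_a, ann_b)
    counter = 0
    for (chrom_a, chrom_b) in sorted(groups):
        pool = groups[(chrom_a, chrom_b)]
        while len(pool) >= 2:
            chosen: tuple[float, list[int], int] | None = None
            for orient in (1, -1):
                pts = [(pa.rank_a, orient * pa.rank_b) for pa in pool]
                scores = (
                    [pa.pair.score if pa.pair.score is not None else 1.0 for pa in pool]
                    if use_anchor_scores
                    else None
                )
                score, idx = best_chain(pts, max_gap, gap_penalty, scores)
                if len(idx) >= 2 and (chosen is None or score > chosen[0] + 1e-9):
                    chosen = (score, idx, orient)
            if chosen is None:
                break
            _, idx, orient = chosen
            members = sorted((pool[i] for i in idx), key=lambda pa: pa.rank_a)
            counter += 1
            blocks.append(
                SyntenicBlock(f"blk{counter:04d}", chrom_a, chrom_b, members, orient)
            )
            taken = set(idx)
            pool = [pa for i, pa in enumerate(pool) if i not in taken]
    kept = [b for b in blocks if b.n_pairs >= min_pairs]
    log.info(
        "chained %d anchors into %d blocks (%d below min_pairs=%d dropped)",
        sum(b.n_pairs for b in blocks),
        len(kept),
        len(blocks) - len(kept),
        min_pairs,
    )
    return kept


# ---------------------------------------------------------------------------
# merging


def _try_merge(x: SyntenicBlock, y: SyntenicBlock, merge_dist: int) -> SyntenicBlock | None:
    """Merge two blocks (x before y in rank_a) if the rank gap between their
    spans is <= merge_dist on both genomes and the union stays monotone."""
    if (x.chrom_a, x.chrom_b, x.orientation) != (y.chrom_a, y.chrom_b, y.orientation):
        return None
    gap_a = y.span_a[0] - x.span_a[1]
    if gap_a > merge_dist:
        return None
    if x.orientation == 1:
        gap_b = y.span_b[0] - x.span_b[1]
    else:
        gap_b = x.span_b[0] - y.span_b[1]
    if gap_b > merge_dist:
        return None
    union = sorted(x.anchors + y.anchors, key=lambda pa: (pa.rank_a, pa.rank_b))
    merged = SyntenicBlock(
        x.block_id,
        x.chrom_a,
        x.chrom_b,
        union,
        x.orientation,
        note=(x.note + " " if x.note else "") + f"merged+{y.block_id}",
    )
    try:
        merged.validate()
    except ValueError:
        return None
    return merged


def _gap_conflict(x: SyntenicBlock, y: SyntenicBlock, others) -> bool:
    """True when a third block sits in the gap between x and y on either
    genome, in which case merging across it would create a block that
    overlaps the intervening one (e.g. flanks of an inversion)."""
    lo_a, hi_a = x.span_a[1] + 1, y.span_a[0] - 1
    if x.orientation == 1:
        lo_b, hi_b = x.span_b[1] + 1, y.span_b[0] - 1
    else:
        lo_b, hi_b = y.span_b[1] + 1, x.span_b[0] - 1
    for b in others:
        if b is x or b is y:
            continue
        if b.chrom_a == x.chrom_a and lo_a <= hi_a:
            s, e = b.span_a
            if s <= hi_a and e >= lo_a:
                return True
        if b.chrom_b == x.chrom_b and lo_b <= hi_b:
            s, e = b.span_b
            if s <= hi_b and e >= lo_b:
                return True
    return False


def merge_blocks(blocks, merge_dist: int = 50) -> list[SyntenicBlock]:
    """Merge nearby same-orientation blocks, QuotaAlign-style, to fixpoint.

    A merge is refused when another block lies in the gap being bridged
    (the flanks of an inversion or of an inserted segment stay separate).
    The result is independent of input order: blocks are processed per
    (chromosome pair, orientation) group in span order.
    """
    work = list(blocks)
    changed = True
    while changed:
        changed = False
        groups: dict[tuple[str, str, int], list[SyntenicBlock]] = {}
        for b in work:
            groups.setdefault((b.chrom_a, b.chrom_b, b.orientation), []).append(b)
        nxt_all: list[SyntenicBlock] = []
        for key in sorted(groups):
            items = sorted(groups[key], key=lambda b: (b.span_a, b.span_b, b.block_id))
            nxt: list[SyntenicBlock] = []
            for b in items:
                if nxt and not _gap_conflict(nxt[-1], b, work):
                    merged = _try_merge(nxt[-1], b, merge_dist)
                    if merged is not None:
                        nxt[-1] = merged
                        changed = True
                        continue
                nxt.append(b)
            nxt_all.extend(nxt)
        work = nxt_all
    work.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.span_a, b.span_b))
    return work


def manual_merge(blocks, block_ids) -> SyntenicBlock:
    """Merge the named blocks regardless of distance (the manual escape hatch
    for same-GB fragments QuotaAlign leaves apart).  The union must still be
    a monotone run; a provenance note is recorded on the result."""
    by_id = {b.block_id: b for b in blocks}
    missing = [bid for bid in block_ids if bid not in by_id]
    if missing:
        raise KeyError(f"unknown block ids: {missing}")
    members = [by_id[bid] for bid in block_ids]
    if len(members) == 1:
        return members[0]
    first = members[0]
    for b in members[1:]:
        if (b.chrom_a, b.chrom_b) != (first.chrom_a, first.chrom_b):
            raise ValueError("manual_merge: blocks lie on different chromosome pairs")
        if b.orientation != first.orientation:
            raise ValueError("manual_merge: blocks have opposite orientations")
    union = sorted(
        (pa for b in members for pa in b.anchors), key=lambda pa: (pa.rank_a, pa.rank_b)
    )
    merged = SyntenicBlock(
        first.block_id,
        first.chrom_a,
        first.chrom_b,
        union,
        first.orientation,
        note="manual_merge(" + ",".join(block_ids) + ")",
    )
    merged.validate()  # hard error if the union breaks monotonicity
    return merged
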