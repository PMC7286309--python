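"""Shared builders for compact in-memory test fixtures."""

from __future__ import annotations

from gbkit.io_formats import AnchorPair, GBDefinition, GenomeAnnotation


def make_annotation(
    genome_id: str,
    chrom_sizes: dict[str, int],
    gene_len: int = 100,
    spacing: int = 100,
    min_chrom_len: int = 0,
) -> GenomeAnnotation:
    """Regularly spaced genes named ``{genome}.{chrom}.{rank}``."""
    genes = []
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            start = i * (gene_len + spacing)
            genes.append((f"{genome_id}.{chrom}.{i}", chrom, start, start + gene_len, "+"))
    return GenomeAnnotation.from_genes(genome_id, genes, min_chrom_len=min_chrom_len)


def rank_anchor(ann_a, ann_b, chrom_a, ra, chrom_b, rb, ks=None, ks_max=2.0):
    ga = ann_a.chromosomes[chrom_a].genes[ra].gene_id
    gb = ann_b.chromosomes[chrom_b].genes[rb].gene_id
    return AnchorPair(ga, gb, ks, None, ks is not None and ks < ks_max)


def diagonal_anchors(ann_a, ann_b, chrom_a, chrom_b, pairs, ks=None):
    """Anchors at explicit (rank_a, rank_b) positions; ``pairs`` may also be
    (rank_a, rank_b, ks) triples."""
    out = []
    for p in pairs:
        if len(p) == 3:
            ra, rb, k = p
        else:
            (ra, rb), k = p, ks
        out.append(rank_anchor(ann_a, ann_b, chrom_a, ra, chrom_b, rb, k))
    return out


def gb_def(label, ak_chrom, ref_chrom, rank_start, rank_end, direction=1):
    return GBDefinition(
        label,
        ak_chrom,
        f"ref.{ref_chrom}.{rank_start}",
        f"ref.{ref_chrom}.{rank_end}",
        ref_chrom,
        rank_start,
        rank_end,
        direction,
    )
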