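"""Synthetic crucifer-style genome evolution with full ground truth.

The generator lays out an ancestral karyotype partitioned into labeled
genomic blocks (GBs) on several chromosomes, then evolves it along a
phylogeny: an optional whole-genome duplication (WGD) on a configured
branch doubles every chromosome; biased fractionation deletes duplicate
gene copies; inversions, translocations, fissions and fusions rearrange
each branch's genome.  Every event is logged and per-taxon true painted
karyotypes, adjacency sets and per-anchor origins are returned, so every
downstream stage of the analysis can be scored against truth.

Ks model
--------
Branch lengths are expressed directly in Ks units (expected synonymous
substitutions accumulated along that lineage).  A homologous pair drawn
from genomes X and Y receives a log-normally distributed Ks whose mode is
the patristic distance between X and Y, plus a WGD excess for pairs that
diverged at the duplication rather than at speciation ("additive effect of
lineage-specific substitutions").  The emitted reference genome is the
ancestral arrangement itself, treated as an extant reference lineage
hanging off the root (``ref_branch_ks``) that retained subgenome 1 after
the WGD; subgenome-1 query copies are therefore its orthologs and
subgenome-2 copies its At-alpha-like paralogs.

Determinism: all randomness flows from one integer seed; every branch and
every anchor table draws from its own substream derived from stable name
hashes, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import copy
import json
import logging
import string
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .gb_projection import GBMap, SubBlock, assign_indices
from .io_formats import (
    AnchorPair,
    GBDefinition,
    GenomeAnnotation,
    write_anchors,
    write_gb_map,
    write_gb_table,
    write_gff3,
)

log = logging.getLogger(__name__)

__all__ = [
    "WGDConfig",
    "FractionationConfig",
    "EventCounts",
    "PlannedEvent",
    "SimConfig",
    "Ancestor",
    "GroundTruth",
    "SimResult",
    "simulate_ancestor",
    "evolve_along_tree",
    "simulate_dataset",
    "emit_dataset",
    "DEFAULT_TREE",
]

# Five-taxon backbone: an Aethionema-like first-diverging lineage, an
# Arabideae-like lineage, and lineages III/E, I/A, II/B.  Branch lengths in
# Ks units were chosen so the key pairwise ortholog modes match the printed
# comparisons (Aethionema vs reference 0.77; crown pairs ~0.3-0.5).
DEFAULT_TREE = (
    "(Aeth:0.37,(Arab:0.25,(LinIII:0.20,(LinI:0.15,LinII:0.15)N3:0.05)N2:0.05)N1:0.12)root;"
)


@dataclass
class WGDConfig:
    enabled: bool = False
    ks_mode: float = 0.6  # Ks excess of WGD-derived pairs over the ortholog mode
    ks_logsd: float = 0.2
    branch: str = "root"


@dataclass
class FractionationConfig:
    loss_prob: float = 0.0  # per-branch probability a duplicated gene loses one copy
    copy_bias: float = 0.5  # probability the lost copy is the subgenome-1 (ortholog) one


@dataclass
class EventCounts:
    inversion: int = 0
    translocation: int = 0
    fission: int = 0
    fusion: int = 0


@dataclass
class PlannedEvent:
    """An explicit rearrangement with fixed breakpoints (for planted
    scenarios); coordinates are in the genome state current when the event
    is applied, so list multiple events in an order that keeps indices
    meaningful (e.g. fissions in descending chromosome index)."""

    kind: str  # inversion | translocation | fission | fusion
    chrom: int
    start: int | None = None  # inclusive gene index
    end: int | None = None  # exclusive
    pos: int | None = None  # fission split point
    dest_chrom: int | None = None
    dest_pos: int | None = None
    chrom2: int | None = None  # fusion partner


@dataclass
class SimConfig:
    n_chrom: int = 8
    gbs_per_chrom: tuple[int, ...] | int = (3, 3, 3, 3, 3, 3, 2, 2)  # 22 GBs, ACK-like
    genes_per_gb: int = 100
    tree: str = DEFAULT_TREE
    ref_branch_ks: float = 0.40
    ks_logsd: float = 0.2
    wgd: WGDConfig = field(default_factory=WGDConfig)
    fractionation: FractionationConfig = field(default_factory=FractionationConfig)
    events: EventCounts = field(default_factory=EventCounts)  # default per branch
    branch_events: dict = field(default_factory=dict)  # name -> EventCounts | [PlannedEvent]
    max_event_retries: int = 100
    gene_len: int = 1500
    intergenic: int = 2500
    seed: int = 0

    def gb_counts(self) -> list[int]:
        if isinstance(self.gbs_per_chrom, int):
            return [self.gbs_per_chrom] * self.n_chrom
        counts = list(self.gbs_per_chrom)
        if len(counts) != self.n_chrom:
            raise ValueError("gbs_per_chrom length must equal n_chrom")
        return counts

    @classmethod
    def from_toml(cls, path) -> "SimConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        kwargs = {}
        if "wgd" in raw:
            kwargs["wgd"] = WGDConfig(**raw.pop("wgd"))
        if "fractionation" in raw:
            kwargs["fractionation"] = FractionationConfig(**raw.pop("fractionation"))
        if "events" in raw:
            kwargs["events"] = EventCounts(**raw.pop("events"))
        if "branch_events" in raw:
            be = {}
            for name, spec in raw.pop("branch_events").items():
                if isinstance(spec, list):
                    be[name] = [PlannedEvent(**ev) for ev in spec]
                else:
                    be[name] = EventCounts(**spec)
            kwargs["branch_events"] = be
        if "gbs_per_chrom" in raw and isinstance(raw["gbs_per_chrom"], list):
            raw["gbs_per_chrom"] = tuple(raw["gbs_per_chrom"])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# genome representation


@dataclass(frozen=True)
class SimGene:
    anc_id: int
    sign: int = 1
    subgenome: int = 1


Genome = list  # list[list[SimGene]]


@dataclass
class AncestorMeta:
    """Per-ancestral-gene lookup tables (indexed by anc_id)."""

    gene_ids: list[str]
    labels: list[str]
    chrom_index: list[int]
    chrom_rank: list[int]


@dataclass
class Ancestor:
    genome: Genome
    meta: AncestorMeta
    annotation: GenomeAnnotation
    gb_table: list[GBDefinition]


@dataclass
class EventRecord:
    branch: str
    kind: str
    chrom: int
    detail: str
    n_genes: int


@dataclass
class GroundTruth:
    true_maps: dict  # taxon -> GBMap
    ancestor_map: GBMap
    ref_anchor_origins: dict  # taxon -> {(gene_a, gene_b) -> "ortholog"|"wgd_paralog"}
    events: list


@dataclass
class SimResult:
    config: SimConfig
    ancestor: Ancestor
    annotations: dict  # taxon -> GenomeAnnotation
    ref_anchors: dict  # taxon -> list[AnchorPair]
    pair_anchors: dict  # (taxon_a, taxon_b) -> list[AnchorPair]
    ground_truth: GroundTruth
    genomes: dict = field(default_factory=dict)  # taxon -> internal genome state

    def true_map_at_resolution(
        self, taxon: str, min_run_genes: int = 20, collapse_gap: int = 50
    ) -> GBMap:
        """The taxon's true painted karyotype at analysis resolution:
        fragments below the sub-block floor are invisible and adjacent
        same-label runs separated by less than the merge distance collapse,
        exactly as an ideal detector with those thresholds would report."""
        return build_true_map(
            self.genomes[taxon],
            self.ancestor.meta,
            self.config,
            taxon,
            [f"{taxon}_chr{i + 1}" for i in range(len(self.genomes[taxon]))],
            collapse_gap=collapse_gap,
            min_run_genes=min_run_genes,
            merge_adjacent=True,
        )


def _gb_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    labels = list(letters)
    i = 1
    while len(labels) < n:
        labels.extend(f"{c}{i}" for c in letters)
        i += 1
    return labels[:n]


def _rng_for(seed: int, *names: str) -> np.random.Generator:
    parts = [seed & 0x7FFFFFFF] + [zlib.crc32(n.encode()) & 0x7FFFFFFF for n in names]
    return np.random.default_rng(parts)


def _anc_gene_id(aid: int) -> str:
    return f"anc{aid:05d}"


def _leaf_gene_id(taxon: str, g: SimGene) -> str:
    return f"{taxon}_{g.anc_id:05d}_s{g.subgenome}"


def _layout_annotation(genome: Genome, genome_id: str, chrom_names, cfg: SimConfig, taxon=None):
    """Build a GenomeAnnotation from a genome state with regular gene spacing."""
    step = cfg.gene_len + cfg.intergenic
    genes = []
    lengths = {}
    for ci, chrom in enumerate(genome):
        cname = chrom_names[ci]
        lengths[cname] = max(len(chrom), 1) * step
        for i, g in enumerate(chrom):
            gid = _anc_gene_id(g.anc_id) if taxon is None else _leaf_gene_id(taxon, g)
            start = i * step
            genes.append((gid, cname, start, start + cfg.gene_len, "+" if g.sign > 0 else "-"))
    return GenomeAnnotation.from_genes(genome_id, genes, chrom_lengths=lengths, chrom_order=list(chrom_names))


# ---------------------------------------------------------------------------
# ancestor


def simulate_ancestor(config: SimConfig) -> Ancestor:
    """Lay out the ancestral karyotype: contiguous genes partitioned into
    labeled GB intervals that exactly tile each chromosome."""
    counts = config.gb_counts()
    labels = _gb_labels(sum(counts))
    genome: Genome = []
    gene_ids: list[str] = []
    meta_labels: list[str] = []
    meta_chrom: list[int] = []
    meta_rank: list[int] = []
    gb_table: list[GBDefinition] = []
    aid = 0
    li = 0
    for ci, n_gbs in enumerate(counts):
        chrom: list[SimGene] = []
        ak = f"AK{ci + 1}"
        for _ in range(n_gbs):
            label = labels[li]
            li += 1
            start_rank = len(chrom)
            for _ in range(config.genes_per_gb):
                chrom.append(SimGene(aid))
                gene_ids.append(_anc_gene_id(aid))
                meta_labels.append(label)
                meta_chrom.append(ci)
                meta_rank.append(len(chrom) - 1)
                aid += 1
            gb_table.append(
                GBDefinition(
                    label,
                    ak,
                    _anc_gene_id(chrom[start_rank].anc_id),
                    _anc_gene_id(chrom[-1].anc_id),
                    ak,
                    start_rank,
                    len(chrom) - 1,
                )
            )
        genome.append(chrom)
    chrom_names = [f"AK{ci + 1}" for ci in range(len(genome))]
    ann = _layout_annotation(genome, "ancestor", chrom_names, config)
    meta = AncestorMeta(gene_ids, meta_labels, meta_chrom, meta_rank)
    return Ancestor(genome, meta, ann, gb_table)


# ---------------------------------------------------------------------------
# rearrangement events


def _flip(g: SimGene) -> SimGene:
    return replace(g, sign=-g.sign)


def _apply_inversion(genome: Genome, c: int, a: int, b: int) -> None:
    genome[c][a:b] = [_flip(g) for g in reversed(genome[c][a:b])]


def _apply_translocation(genome: Genome, c: int, a: int, b: int, d: int, p: int) -> None:
    seg = genome[c][a:b]
    del genome[c][a:b]
    genome[d][p:p] = seg


def _apply_fission(genome: Genome, c: int, p: int) -> None:
    left, right = genome[c][:p], genome[c][p:]
    genome[c] = left
    genome.insert(c + 1, right)


def _apply_fusion(genome: Genome, c1: int, c2: int) -> None:
    if c1 == c2:
        raise ValueError("fusion needs two distinct chromosomes")
    lo, hi = sorted((c1, c2))
    genome[lo] = genome[c1] + genome[c2]
    del genome[hi]


def _apply_planned(genome: Genome, ev: PlannedEvent, branch: str, events: list) -> None:
    if ev.kind == "inversion":
        _apply_inversion(genome, ev.chrom, ev.start, ev.end)
        events.append(EventRecord(branch, "inversion", ev.chrom, f"[{ev.start},{ev.end})", ev.end - ev.start))
    elif ev.kind == "translocation":
        _apply_translocation(genome, ev.chrom, ev.start, ev.end, ev.dest_chrom, ev.dest_pos)
        events.append(
            EventRecord(
                branch, "translocation", ev.chrom,
                f"[{ev.start},{ev.end})->chr{ev.dest_chrom}@{ev.dest_pos}", ev.end - ev.start,
            )
        )
    elif ev.kind == "fission":
        _apply_fission(genome, ev.chrom, ev.pos)
        events.append(EventRecord(branch, "fission", ev.chrom, f"@{ev.pos}", ev.pos))
    elif ev.kind == "fusion":
        n = len(genome[ev.chrom])
        _apply_fusion(genome, ev.chrom, ev.chrom2)
        events.append(EventRecord(branch, "fusion", ev.chrom, f"+chr{ev.chrom2}", n))
    else:
        raise ValueError(f"unknown event kind {ev.kind!r}")


def _sample_events(genome: Genome, counts: EventCounts, branch: str, rng, events: list, retries: int) -> None:
    def pick_chrom(min_genes=1):
        for _ in range(retries):
            c = int(rng.integers(len(genome)))
            if len(genome[c]) >= min_genes:
                return c
        raise RuntimeError(f"branch {branch}: no chromosome with >= {min_genes} genes after {retries} tries")

    for _ in range(counts.inversion):
        c = pick_chrom(2)
        n = len(genome[c])
        a, b = sorted(int(x) for x in rng.choice(n + 1, size=2, replace=False))
        _apply_inversion(genome, c, a, b)
        events.append(EventRecord(branch, "inversion", c, f"[{a},{b})", b - a))
    for _ in range(counts.translocation):
        for attempt in range(retries):
            c = pick_chrom(2)
            n = len(genome[c])
            a, b = sorted(int(x) for x in rng.choice(n + 1, size=2, replace=False))
            if b - a < n:  # do not move a whole chromosome
                break
        else:
            raise RuntimeError(f"branch {branch}: could not sample a translocation segment")
        seg = genome[c][a:b]
        del genome[c][a:b]
        d = pick_chrom(0)
        p = int(rng.integers(len(genome[d]) + 1))
        genome[d][p:p] = seg
        events.append(EventRecord(branch, "translocation", c, f"[{a},{b})->chr{d}@{p}", len(seg)))
    for _ in range(counts.fission):
        c = pick_chrom(2)
        p = int(rng.integers(1, len(genome[c])))
        _apply_fission(genome, c, p)
        events.append(EventRecord(branch, "fission", c, f"@{p}", p))
    for _ in range(counts.fusion):
        if len(genome) < 2:
            log.warning("branch %s: fusion skipped, single chromosome", branch)
            continue
        c1, c2 = (int(x) for x in rng.choice(len(genome), size=2, replace=False))
        n = len(genome[c1])
        _apply_fusion(genome, c1, c2)
        events.append(EventRecord(branch, "fusion", c1, f"+chr{c2}", n))


def _apply_branch(genome: Genome, branch: str, cfg: SimConfig, events: list) -> Genome:
    genome = [list(chrom) for chrom in genome]
    rng = _rng_for(cfg.seed, "branch", branch)
    if cfg.wgd.enabled and branch == cfg.wgd.branch:
        genome.extend([[replace(g, subgenome=2) for g in chrom] for chrom in genome])
        events.append(EventRecord(branch, "wgd", -1, "whole-genome duplication", sum(len(c) for c in genome)))
    # biased fractionation of duplicate pairs
    if cfg.wgd.enabled and cfg.fractionation.loss_prob > 0:
        present: dict[tuple[int, int], int] = {}
        for chrom in genome:
            for g in chrom:
                present[(g.anc_id, g.subgenome)] = present.get((g.anc_id, g.subgenome), 0) + 1
        dup_ids = sorted(
            aid for aid in {k[0] for k in present}
            if (aid, 1) in present and (aid, 2) in present
        )
        victims: set[tuple[int, int]] = set()
        for aid in dup_ids:
            if rng.random() < cfg.fractionation.loss_prob:
                sub = 1 if rng.random() < cfg.fractionation.copy_bias else 2
                victims.add((aid, sub))
        if victims:
            genome = [
                [g for g in chrom if (g.anc_id, g.subgenome) not in victims]
                for chrom in genome
            ]
    spec = cfg.branch_events.get(branch, cfg.events)
    if isinstance(spec, list):
        for ev in spec:
            _apply_planned(genome, ev, branch, events)
    else:
        _sample_events(genome, spec, branch, rng, events, cfg.max_event_retries)
    return [chrom for chrom in genome if chrom]  # drop emptied chromosomes


# ---------------------------------------------------------------------------
# ground truth painted karyotypes


def build_true_map(
    genome: Genome,
    meta: AncestorMeta,
    cfg: SimConfig,
    genome_id: str,
    chrom_names,
    collapse_gap: int = 50,
    min_run_genes: int = 1,
    subgenome: int = 1,
    merge_adjacent: bool = False,
) -> GBMap:
    """Segment a genome state into its true sub-blocks.

    A run extends while the GB label and strand sign stay constant, the
    ancestral rank advances in the direction given by the sign, and both the
    ancestral-rank step and the query gap stay within ``collapse_gap`` (the
    resolution at which the analysis merges blocks, so truth and inference
    are compared at the same scale).  Only genes of ``subgenome`` are
    painted: they are the copies orthologous to the reference.

    With ``merge_adjacent`` (analysis-resolution truth), after dropping runs
    below ``min_run_genes``, consecutive same-label same-orientation runs
    whose query and reference gaps are within ``collapse_gap`` are collapsed
    into one fragment -- a sub-resolution fragment between them cannot be
    seen by any detector with that floor.
    """
    step_bp = cfg.gene_len + cfg.intergenic
    fragments: list[SubBlock] = []
    for ci, chrom in enumerate(genome):
        run: list[tuple[int, SimGene]] = []
        run_dir = 0  # ancestral-rank step direction; 0 = single gene so far

        def close_run():
            nonlocal run_dir
            if len(run) < min_run_genes:
                run.clear()
                run_dir = 0
                return
            idxs = [i for i, _ in run]
            arks = [meta.chrom_rank[g.anc_id] for _, g in run]
            g0 = run[0][1]
            fragments.append(
                SubBlock(
                    gb_label=meta.labels[g0.anc_id],
                    index=0,
                    chrom=chrom_names[ci],
                    rank_start=idxs[0],
                    rank_end=idxs[-1],
                    bp_start=idxs[0] * step_bp,
                    bp_end=idxs[-1] * step_bp + cfg.gene_len,
                    # inversion is visible to a rank-space detector only as
                    # reversed gene order, so truth uses the rank direction
                    # (strand sign breaks ties for single-gene runs)
                    inverted=run_dir < 0 if run_dir != 0 else g0.sign < 0,
                    ambiguous=run_dir == 0,
                    n_genes=len(run),
                    ref_chrom=f"AK{meta.chrom_index[g0.anc_id] + 1}",
                    ref_start=min(arks),
                    ref_end=max(arks),
                )
            )
            run.clear()
            run_dir = 0

        for i, g in enumerate(chrom):
            if g.subgenome != subgenome:
                continue
            if run:
                pi, pg = run[-1]
                step = meta.chrom_rank[g.anc_id] - meta.chrom_rank[pg.anc_id]
                ok = (
                    meta.labels[g.anc_id] == meta.labels[pg.anc_id]
                    and step != 0
                    and (run_dir == 0 or step * run_dir > 0)
                    and abs(step) <= collapse_gap
                    and i - pi <= collapse_gap
                )
                if not ok:
                    close_run()
                elif run_dir == 0:
                    run_dir = 1 if step > 0 else -1
            run.append((i, g))
        close_run()
    if merge_adjacent:
        by_chrom: dict[str, list[SubBlock]] = {}
        for f in fragments:
            by_chrom.setdefault(f.chrom, []).append(f)
        merged: list[SubBlock] = []
        for subs in by_chrom.values():
            subs.sort(key=lambda s: s.rank_start)
            acc: list[SubBlock] = []
            for f in subs:
                if acc:
                    p = acc[-1]
                    qgap = f.rank_start - p.rank_end - 1
                    if p.inverted:
                        rgap = p.ref_start - f.ref_end - 1
                    else:
                        rgap = f.ref_start - p.ref_end - 1
                    if (
                        p.gb_label == f.gb_label
                        and p.inverted == f.inverted
                        and 0 <= qgap <= collapse_gap
                        and 0 <= rgap <= collapse_gap
                    ):
                        p.rank_end = f.rank_end
                        p.bp_end = f.bp_end
                        p.ref_start = min(p.ref_start, f.ref_start)
                        p.ref_end = max(p.ref_end, f.ref_end)
                        p.n_genes += f.n_genes
                        continue
                acc.append(f)
            merged.extend(acc)
        fragments = merged
    assign_indices(fragments)
    chrom_map: dict[str, list[SubBlock]] = {}
    for f in fragments:
        chrom_map.setdefault(f.chrom, []).append(f)
    for subs in chrom_map.values():
        subs.sort(key=lambda s: s.rank_start)
    return GBMap(genome_id, chrom_map)


# ---------------------------------------------------------------------------
# evolution along the tree


def _node_name(node, fallback: str) -> str:
    if node.is_leaf() and node.taxon is not None:
        return node.taxon.label
    return node.label or fallback


def _draw_ks(rng, mode: float, logsd: float) -> float:
    return float(np.exp(rng.normal(np.log(mode) + logsd**2, logsd)))


def evolve_along_tree(ancestor: Ancestor, config: SimConfig) -> SimResult:
    """Evolve the ancestor along the configured tree and emit per-taxon
    annotations, anchor tables with Ks, and ground truth."""
    tree = dendropy.Tree.get(data=config.tree, schema="newick", preserve_underscores=True)
    events: list[EventRecord] = []
    root_name = _node_name(tree.seed_node, "root")
    genomes: dict[str, Genome] = {}

    counter = [0]

    def descend(node, genome: Genome) -> None:
        for child in node.child_nodes():
            counter[0] += 1
            name = _node_name(child, f"node{counter[0]}")
            child_genome = _apply_branch(genome, name, config, events)
            if child.is_leaf():
                genomes[name] = child_genome
            else:
                descend(child, child_genome)

    root_genome = _apply_branch(ancestor.genome, root_name, config, events)
    descend(tree.seed_node, root_genome)

    taxa = sorted(genomes)
    # patristic distances between leaves, and leaf depths below the root
    pdm = tree.phylogenetic_distance_matrix()
    tax_ns = {t.label: t for t in tree.taxon_namespace}
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depth[leaf.taxon.label] = d

    annotations = {}
    chrom_names_of = {}
    for taxon in taxa:
        names = [f"{taxon}_chr{i + 1}" for i in range(len(genomes[taxon]))]
        chrom_names_of[taxon] = names
        annotations[taxon] = _layout_annotation(genomes[taxon], taxon, names, config, taxon=taxon)

    wgd_excess = config.wgd.ks_mode if config.wgd.enabled else 0.0

    ref_anchors: dict[str, list[AnchorPair]] = {}
    origins: dict[str, dict] = {}
    for taxon in taxa:
        rng = _rng_for(config.seed, "ks", "ref", taxon)
        dist = depth[taxon] + config.ref_branch_ks
        pairs, orig = [], {}
        for chrom in genomes[taxon]:
            for g in chrom:
                mode = dist + (wgd_excess if g.subgenome == 2 else 0.0)
                logsd = config.wgd.ks_logsd if g.subgenome == 2 else config.ks_logsd
                ks = _draw_ks(rng, mode, logsd)
                ga, gb = _leaf_gene_id(taxon, g), _anc_gene_id(g.anc_id)
                pairs.append(AnchorPair(ga, gb, ks, None, ks < 2.0))
                orig[(ga, gb)] = "ortholog" if g.subgenome == 1 else "wgd_paralog"
        ref_anchors[taxon] = pairs
        origins[taxon] = orig

    pair_anchors: dict[tuple[str, str], list[AnchorPair]] = {}
    for i, ta in enumerate(taxa):
        index_a: dict[int, list[SimGene]] = {}
        for chrom in genomes[ta]:
            for g in chrom:
                index_a.setdefault(g.anc_id, []).append(g)
        for tb in taxa[i + 1 :]:
            rng = _rng_for(config.seed, "ks", ta, tb)
            dist = pdm.patristic_distance(tax_ns[ta], tax_ns[tb])
            pairs = []
            for chrom in genomes[tb]:
                for gb_gene in chrom:
                    for ga_gene in index_a.get(gb_gene.anc_id, ()):
                        paralog = ga_gene.subgenome != gb_gene.subgenome
                        mode = dist + (wgd_excess if paralog else 0.0)
                        logsd = config.wgd.ks_logsd if paralog else config.ks_logsd
                        ks = _draw_ks(rng, mode, logsd)
                        pairs.append(
                            AnchorPair(
                                _leaf_gene_id(ta, ga_gene),
                                _leaf_gene_id(tb, gb_gene),
                                ks,
                                None,
                                ks < 2.0,
                            )
                        )
            pair_anchors[(ta, tb)] = pairs

    true_maps = {
        taxon: build_true_map(
            genomes[taxon], ancestor.meta, config, taxon, chrom_names_of[taxon]
        )
        for taxon in taxa
    }
    ancestor_map = build_true_map(
        ancestor.genome,
        ancestor.meta,
        config,
        "ancestor",
        [f"AK{i + 1}" for i in range(len(ancestor.genome))],
    )
    truth = GroundTruth(true_maps, ancestor_map, origins, events)
    return SimResult(
        config, ancestor, annotations, ref_anchors, pair_anchors, truth, genomes
    )


def simulate_dataset(config: SimConfig) -> SimResult:
    """Convenience wrapper: ancestor + evolution in one call."""
    return evolve_along_tree(simulate_ancestor(config), config)


def study_config(seed: int = 0) -> SimConfig:
    """The full study conditions: a 22-block, 8-chromosome ancestor evolved
    along the five-lineage backbone with a shared WGD, biased fractionation
    and moderate per-branch rearrangement (five inversions, two
    translocations, one fission and one fusion per branch), sized so the
    Aethionema-like lineage shows Ks modes near 0.77 (orthologs) and 1.37
    (WGD paralogs) against the reference."""
    return SimConfig(
        seed=seed,
        wgd=WGDConfig(enabled=True, ks_mode=0.6),
        fractionation=FractionationConfig(loss_prob=0.35, copy_bias=0.65),
        events=EventCounts(inversion=5, translocation=2, fission=1, fusion=1),
    )


# ---------------------------------------------------------------------------
# emission


def emit_dataset(result: SimResult, outdir) -> Path:
    """Write the simulated dataset in the package's external formats:
    GFF3 per genome, anchors TSV per leaf pair and per leaf-vs-reference,
    the GB definition table, ground-truth maps/events and a config echo.
    All files re-load through io_formats."""
    outdir = Path(outdir)
    (outdir / "anchors").mkdir(parents=True, exist_ok=True)
    (outdir / "ref_anchors").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    write_gff3(result.ancestor.annotation, outdir / "ancestor.gff3")
    write_gb_table(result.ancestor.gb_table, outdir / "gb_table.tsv")
    for taxon, ann in sorted(result.annotations.items()):
        write_gff3(ann, outdir / f"{taxon}.gff3")
    for (ta, tb), pairs in sorted(result.pair_anchors.items()):
        write_anchors(pairs, outdir / "anchors" / f"{ta}__{tb}.tsv")
    for taxon, pairs in sorted(result.ref_anchors.items()):
        write_anchors(pairs, outdir / "ref_anchors" / f"{taxon}.tsv")
    for taxon, m in sorted(result.ground_truth.true_maps.items()):
        write_gb_map(m, outdir / "truth" / f"{taxon}.map.tsv")
    write_gb_map(result.ground_truth.ancestor_map, outdir / "truth" / "ancestor.map.tsv")
    with open(outdir / "truth" / "events.tsv", "w") as fh:
        fh.write("branch\tkind\tchrom\tdetail\tn_genes\n")
        for e in result.ground_truth.events:
            fh.write(f"{e.branch}\t{e.kind}\t{e.chrom}\t{e.detail}\t{e.n_genes}\n")
    for taxon, orig in sorted(result.ground_truth.ref_anchor_origins.items()):
        with open(outdir / "truth" / f"origins_{taxon}.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\torigin\n")
            for (ga, gb), o in orig.items():
                fh.write(f"{ga}\t{gb}\t{o}\n")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
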