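"""End-to-end pipeline: load -> chain -> merge -> classify -> dedup ->
project -> adjacencies -> parsimony ranking, with config echo and per-stage
logging.  The pipeline is a pure function of (inputs, config, seed)."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import adjacency as adj
from . import chaining, gb_projection, io_formats, ks_classify
from .chaining import Origin

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineInputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters.  Defaults are the genomic-block detection
    settings used throughout: DAGchainer-style max gap 25 gene ranks,
    20 retained pairs per block, QuotaAlign-style merge distance 50 genes,
    5 Mb minimum chromosome length, Ks ceiling 2."""

    max_gap: int = 25
    min_pairs: int = 20
    merge_dist: int = 50
    min_chrom_len: int = 5_000_000
    ks_max: float = 2.0
    cut: float | None = None  # manual classification cut; None = estimate
    min_subblock: int = 20
    allow_small: tuple[str, ...] = ("G",)
    adjacency_mode: str = "lenient"  # or "strict"
    adjacency_max_gap: int = 50
    gap_penalty: float = 0.2
    overlap_frac: float = 0.5
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "allow_small" in raw:
            raw = {**raw, "allow_small": tuple(raw["allow_small"])}
        return cls(**raw)


@dataclass
class PipelineInputs:
    ref_annotation: str | Path
    gb_table: str | Path
    queries: dict  # taxon -> (annotation_path, ref_anchors_path)
    trees: str | Path | None = None
    ref_min_chrom_len: int | None = None  # defaults to config.min_chrom_len


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, outdir) -> dict:
    """Run every stage for every query genome; write per-stage TSVs and a
    config echo into ``outdir`` and return a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"taxa": {}}

    ref_ann = io_formats.read_annotation(
        inputs.ref_annotation,
        min_chrom_len=(
            config.min_chrom_len
            if inputs.ref_min_chrom_len is None
            else inputs.ref_min_chrom_len
        ),
        genome_id="reference",
    )
    gb_table = io_formats.read_gb_table(inputs.gb_table, ref_ann)
    log.info("reference: %d chromosomes, %d genes, %d GBs",
             len(ref_ann.chromosomes), ref_ann.n_genes, len(gb_table))

    maps = {}
    for taxon in sorted(inputs.queries):
        ann_path, anchors_path = inputs.queries[taxon]
        ann = io_formats.read_annotation(
            ann_path, min_chrom_len=config.min_chrom_len, genome_id=taxon
        )
        anchors = io_formats.read_anchors(anchors_path, ann, ref_ann, config.ks_max)
        blocks = chaining.chain_anchors(
            anchors,
            ann,
            ref_ann,
            max_gap=config.max_gap,
            min_pairs=config.min_pairs,
            gap_penalty=config.gap_penalty,
        )
        blocks = chaining.merge_blocks(blocks, merge_dist=config.merge_dist)

        if config.cut is not None:
            modes = ks_classify.KsModes(0.0, None, config.cut, config.ks_max)
        else:
            modes = ks_classify.estimate_ks_modes(anchors, ks_max=config.ks_max)
        if modes.cut is None:
            # unimodal Ks: no WGD signal; every block with usable Ks is an ortholog
            log.warning("%s: unimodal Ks (mode %.3f); all blocks treated as ortholog",
                        taxon, modes.ortholog_mode)
            for b in blocks:
                b.median_ks = ks_classify.block_median_ks(b, config.ks_max)
                b.mean_ks = ks_classify.block_mean_ks(b, config.ks_max)
                b.origin = Origin.ORTHOLOG if b.median_ks is not None else Origin.UNCLASSIFIED
        else:
            ks_classify.classify_blocks(blocks, modes)
        blocks = ks_classify.deduplicate_blocks(blocks, overlap_frac=config.overlap_frac)
        io_formats.write_blocks(blocks, outdir / f"blocks_{taxon}.tsv")

        gb_map = gb_projection.build_gb_map(
            blocks,
            gb_table,
            ann,
            min_subblock=config.min_subblock,
            allow_small=frozenset(config.allow_small),
        )
        io_formats.write_gb_map(gb_map, outdir / f"gbmap_{taxon}.tsv")
        maps[taxon] = gb_map

        n_ortho = sum(1 for b in blocks if b.origin == Origin.ORTHOLOG)
        summary["taxa"][taxon] = {
            "n_anchors": len(anchors),
            "n_blocks": len(blocks),
            "n_ortholog_blocks": n_ortho,
            "n_syntenic_genes": sum(
                b.n_pairs for b in blocks if b.origin == Origin.ORTHOLOG
            ),
            "n_sub_blocks": gb_map.n_sub_blocks,
            "ortholog_mode": modes.ortholog_mode,
            "wgd_mode": modes.wgd_mode,
            "cut": modes.cut,
        }
        log.info("%s: %d blocks (%d ortholog), %d sub-blocks",
                 taxon, len(blocks), n_ortho, gb_map.n_sub_blocks)

    if len(maps) >= 2:
        ref_adj = adj.reference_adjacencies(gb_table)
        presence = adj.shared_derived_adjacencies(
            maps,
            ref_adj,
            max_gap_genes=config.adjacency_max_gap,
            strict=config.adjacency_mode == "strict",
        )
        presence.to_csv(outdir / "adjacencies.tsv", sep="\t", index_label="adjacency")
        summary["n_shared_derived_adjacencies"] = int(presence["shared"].sum())

        if inputs.trees is not None:
            topologies = adj.read_topologies(inputs.trees)
            matrix = adj.build_character_matrix(presence)
            if matrix.cells.shape[1] > 0 and len(topologies) >= 2:
                ranking = adj.rank_topologies(matrix, topologies)
                with open(outdir / "topology_ranking.tsv", "w") as fh:
                    fh.write("rank\tscore\tnewick\n")
                    for i, (tree, score) in enumerate(ranking, 1):
                        fh.write(
                            f"{i}\t{score}\t{tree.as_string(schema='newick').strip()}\n"
                        )
                summary["topology_scores"] = [s for _, s in ranking]
            else:
                log.warning("no shared derived characters or <2 topologies; ranking skipped")

    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
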