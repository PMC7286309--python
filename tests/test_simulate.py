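"""Synthetic genome evolution: ancestor layout, event bookkeeping, Ks
structure, fractionation bias, emission round-trips and determinism."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from gbkit.io_formats import read_annotation, read_anchors, read_gb_map, read_gb_table
from gbkit.simulate import (
    EventCounts,
    FractionationConfig,
    PlannedEvent,
    SimConfig,
    WGDConfig,
    emit_dataset,
    simulate_ancestor,
    simulate_dataset,
)


def dir_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestAncestor:
    def test_block_and_gene_arithmetic(self):
        cfg = SimConfig(n_chrom=8, gbs_per_chrom=3, genes_per_gb=100)
        anc = simulate_ancestor(cfg)
        assert len(anc.gb_table) == 24
        assert anc.annotation.n_genes == 2400
        assert len(anc.annotation.chromosomes) == 8

    def test_default_layout_matches_the_22_block_karyotype(self):
        anc = simulate_ancestor(SimConfig())
        assert len(anc.gb_table) == 22
        assert [d.label for d in anc.gb_table[:3]] == ["A", "B", "C"]
        assert len({d.ak_chrom for d in anc.gb_table}) == 8

    def test_gb_intervals_partition_each_chromosome(self):
        cfg = SimConfig(n_chrom=4, gbs_per_chrom=(2, 3, 1, 2), genes_per_gb=30)
        anc = simulate_ancestor(cfg)
        by_chrom = {}
        for d in anc.gb_table:
            by_chrom.setdefault(d.ref_chrom, []).append(d)
        for chrom_id, chrom in anc.annotation.chromosomes.items():
            defs = sorted(by_chrom[chrom_id], key=lambda d: d.rank_start)
            assert defs[0].rank_start == 0
            assert defs[-1].rank_end == chrom.n_genes - 1
            for prev, cur in zip(defs, defs[1:]):
                assert cur.rank_start == prev.rank_end + 1  # no gap, no overlap

    def test_same_seed_reproduces_the_ancestor(self):
        a1 = simulate_ancestor(SimConfig(seed=5))
        a2 = simulate_ancestor(SimConfig(seed=5))
        assert a1.annotation == a2.annotation
        assert a1.gb_table == a2.gb_table


class TestEvolution:
    def test_identity_evolution_returns_ancestral_order_everywhere(self, tiny_tree):
        res = simulate_dataset(SimConfig(seed=1, tree=tiny_tree))
        anc_order = [[g.anc_id for g in chrom] for chrom in res.ancestor.genome]
        for taxon, genome in res.genomes.items():
            assert [[g.anc_id for g in chrom] for chrom in genome] == anc_order
        for taxon, origins in res.ground_truth.ref_anchor_origins.items():
            assert set(origins.values()) == {"ortholog"}

    def test_wgd_with_full_retention_doubles_every_gene(self, tiny_tree):
        res = simulate_dataset(
            SimConfig(seed=1, tree=tiny_tree, wgd=WGDConfig(enabled=True, ks_mode=0.6))
        )
        n_anc = res.ancestor.annotation.n_genes
        for taxon, ann in res.annotations.items():
            assert ann.n_genes == 2 * n_anc
        # ortholog and paralog anchor Ks are well separated
        pairs = res.ref_anchors["A"]
        origin = res.ground_truth.ref_anchor_origins["A"]
        ortho = [p.ks for p in pairs if origin[(p.gene_a, p.gene_b)] == "ortholog"]
        para = [p.ks for p in pairs if origin[(p.gene_a, p.gene_b)] == "wgd_paralog"]
        assert len(ortho) == len(para) == n_anc
        assert np.median(para) - np.median(ortho) > 0.4

    def test_planted_inversions_add_two_boundaries_each(self, tiny_tree):
        # three inversions strictly inside distinct GBs of distinct chromosomes
        events = [
            PlannedEvent("inversion", chrom=0, start=10, end=40),
            PlannedEvent("inversion", chrom=1, start=110, end=150),
            PlannedEvent("inversion", chrom=2, start=30, end=80),
        ]
        res = simulate_dataset(SimConfig(seed=1, tree=tiny_tree, branch_events={"A": events}))
        anc_map = res.ground_truth.ancestor_map
        a_map = res.ground_truth.true_maps["A"]
        assert a_map.n_sub_blocks == anc_map.n_sub_blocks + 2 * len(events)
        inverted = [sb for sb in a_map.sub_blocks() if sb.inverted]
        assert len(inverted) == len(events)
        logged = [e for e in res.ground_truth.events if e.kind == "inversion"]
        assert len(logged) == len(events)
        # other leaves untouched
        assert res.ground_truth.true_maps["B"].n_sub_blocks == anc_map.n_sub_blocks

    def test_fission_and_fusion_change_chromosome_number(self, tiny_tree):
        res = simulate_dataset(
            SimConfig(
                seed=3,
                tree=tiny_tree,
                branch_events={
                    "A": EventCounts(fission=2),
                    "B": EventCounts(fusion=1),
                },
            )
        )
        n_anc = len(res.ancestor.genome)
        assert len(res.genomes["A"]) == n_anc + 2
        assert len(res.genomes["B"]) == n_anc - 1
        assert len(res.genomes["C"]) == n_anc

    def test_biased_fractionation_depletes_the_ortholog_copies(self, tiny_tree):
        res = simulate_dataset(
            SimConfig(
                seed=2,
                tree=tiny_tree,
                wgd=WGDConfig(enabled=True),
                fractionation=FractionationConfig(loss_prob=0.6, copy_bias=0.8),
            )
        )
        for taxon, genome in res.genomes.items():
            sub1 = sum(1 for chrom in genome for g in chrom if g.subgenome == 1)
            sub2 = sum(1 for chrom in genome for g in chrom if g.subgenome == 2)
            assert sub1 < sub2  # ortholog blocks end up with fewer syntenic genes

    def test_ortholog_ks_grows_with_divergence(self):
        res = simulate_dataset(SimConfig(seed=4))
        med = {}
        for (ta, tb), pairs in res.pair_anchors.items():
            med[(ta, tb)] = np.median([p.ks for p in pairs])
        # sister crown lineages are closer than either is to Aethionema
        assert med[("LinI", "LinII")] < med[("Aeth", "LinI")]
        assert med[("Arab", "LinIII")] < med[("Aeth", "Arab")]


class TestEmission:
    def test_three_taxon_run_emits_expected_files(self, tmp_path, tiny_tree):
        res = simulate_dataset(SimConfig(seed=1, tree=tiny_tree))
        out = emit_dataset(res, tmp_path / "sim")
        leaf_gffs = sorted(p.name for p in out.glob("*.gff3"))
        assert leaf_gffs == ["A.gff3", "B.gff3", "C.gff3", "ancestor.gff3"]
        assert len(list((out / "anchors").glob("*.tsv"))) == 3  # C(3,2) leaf pairs
        assert len(list((out / "ref_anchors").glob("*.tsv"))) == 3
        assert (out / "gb_table.tsv").exists() and (out / "config.json").exists()

    def test_emitted_files_reload_through_io_formats(self, tmp_path, tiny_tree):
        res = simulate_dataset(SimConfig(seed=1, tree=tiny_tree))
        out = emit_dataset(res, tmp_path / "sim")
        ref = read_annotation(out / "ancestor.gff3", genome_id="ancestor")
        assert ref == res.ancestor.annotation
        table = read_gb_table(out / "gb_table.tsv", ref)
        assert table == res.ancestor.gb_table
        ann_a = read_annotation(out / "A.gff3", genome_id="A")
        assert ann_a == res.annotations["A"]
        pairs = read_anchors(out / "ref_anchors" / "A.tsv", ann_a, ref)
        assert len(pairs) == len(res.ref_anchors["A"])
        truth_map = read_gb_map(out / "truth" / "A.map.tsv", genome_id="A")
        assert truth_map == res.ground_truth.true_maps["A"]

    def test_fixed_seed_gives_byte_identical_output(self, tmp_path, tiny_tree):
        cfg = dict(seed=9, tree=tiny_tree, events=EventCounts(inversion=2, translocation=1))
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        emit_dataset(simulate_dataset(SimConfig(**cfg)), d1)
        emit_dataset(simulate_dataset(SimConfig(**cfg)), d2)
        assert dir_digest(d1) == dir_digest(d2)

    def test_different_seeds_differ(self, tmp_path, tiny_tree):
        cfg = dict(tree=tiny_tree, events=EventCounts(inversion=2))
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        emit_dataset(simulate_dataset(SimConfig(seed=1, **cfg)), d1)
        emit_dataset(simulate_dataset(SimConfig(seed=2, **cfg)), d2)
        assert dir_digest(d1) != dir_digest(d2)


class TestConfig:
    def test_toml_round_trip_with_nested_sections(self, tmp_path):
        p = tmp_path / "sim.toml"
        p.write_text(
            "seed = 7\nn_chrom = 3\ngbs_per_chrom = [2, 2, 1]\ngenes_per_gb = 30\n"
            'tree = "(A:0.3,(B:0.2,C:0.2)N1:0.1)root;"\n'
            "[wgd]\nenabled = true\nks_mode = 0.5\n"
            "[events]\ninversion = 2\n"
        )
        cfg = SimConfig.from_toml(p)
        assert cfg.seed == 7 and cfg.wgd.enabled and cfg.events.inversion == 2
        assert cfg.gb_counts() == [2, 2, 1]

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "sim.toml"
        p.write_text("seed = 7\nnot_a_key = 1\n")
        with pytest.raises(ValueError, match="not_a_key"):
            SimConfig.from_toml(p)
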