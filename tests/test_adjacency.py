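"""Adjacency characters, shared derived associations, and small-parsimony
scoring against exhaustive enumeration."""

import itertools

import dendropy
import numpy as np
import pytest

from gbkit.adjacency import (
    Adjacency,
    CharacterMatrix,
    build_character_matrix,
    extract_adjacencies,
    fitch_score,
    rank_topologies,
    reference_adjacencies,
    shared_derived_adjacencies,
)
from gbkit.gb_projection import GBMap, SubBlock
from gbkit.simulate import SimConfig, simulate_dataset

from helpers import gb_def


def sub(label, start, end, inverted=False, chrom="c1", ref_start=0, ref_end=10):
    return SubBlock(
        label, 1, chrom, start, end, -1, -1, inverted, False, end - start + 1,
        "AK1", ref_start, ref_end,
    )


def painted(chrom_layout):
    """GBMap from {chrom: [(label, start, end, inverted), ...]}."""
    return GBMap(
        "g",
        {
            chrom: [sub(lab, s, e, inv, chrom=chrom) for lab, s, e, inv in subs]
            for chrom, subs in chrom_layout.items()
        },
    )


class TestExtractAdjacencies:
    def test_three_block_chromosome_yields_both_consecutive_pairs(self):
        m = painted({"c1": [("J", 0, 9, False), ("V", 10, 19, False), ("O", 20, 29, False)]})
        adj = extract_adjacencies(m)
        labels = {frozenset((a.endpoint_1[0], a.endpoint_2[0])) for a in adj}
        assert labels == {frozenset("JV"), frozenset("VO")}

    def test_single_sub_block_chromosome_has_no_adjacency(self):
        assert extract_adjacencies(painted({"c1": [("J", 0, 9, False)]})) == set()

    def test_gap_above_threshold_breaks_the_adjacency(self):
        m = painted({"c1": [("J", 0, 9, False), ("V", 80, 99, False)]})
        assert extract_adjacencies(m, max_gap_genes=50) == set()
        assert len(extract_adjacencies(m, max_gap_genes=70)) == 1

    def test_inversion_flips_the_facing_extremity(self):
        upright = extract_adjacencies(
            painted({"c1": [("J", 0, 9, False), ("V", 10, 19, False)]})
        )
        flipped = extract_adjacencies(
            painted({"c1": [("J", 0, 9, False), ("V", 10, 19, True)]})
        )
        assert upright == {Adjacency.make(("J", "tail"), ("V", "head"))}
        assert flipped == {Adjacency.make(("J", "tail"), ("V", "tail"))}

    def test_identity_painting_recovers_the_reference_adjacencies(self):
        res = simulate_dataset(SimConfig(seed=1, tree="(A:0.3,(B:0.2,C:0.2)N1:0.1)root;"))
        table = res.ancestor.gb_table
        ref_adj = reference_adjacencies(table)
        identity = extract_adjacencies(res.ground_truth.ancestor_map)
        assert identity == ref_adj
        assert Adjacency.make(("A", "tail"), ("B", "head")) in ref_adj
        assert Adjacency.make(("G", "tail"), ("H", "head")) in ref_adj
        # 22 GBs on 8 chromosomes leave 14 within-chromosome neighbour pairs
        assert len(ref_adj) == 14


class TestSharedDerived:
    def maps(self):
        m1 = painted({"c1": [("U", 0, 9, False), ("B", 10, 19, False)]})
        m2 = painted({"c2": [("U", 0, 9, False), ("B", 10, 19, False)]})
        m3 = painted({"c3": [("U", 0, 9, False), ("C", 10, 19, False)]})
        return {"t1": m1, "t2": m2, "t3": m3}

    def test_adjacency_in_two_taxa_absent_from_reference_is_shared(self):
        table = shared_derived_adjacencies(self.maps(), reference=set())
        row = table.loc["B.head--U.tail"]
        assert row["shared"] and row["n_taxa"] == 2
        assert row["t1"] and row["t2"] and not row["t3"]

    def test_single_taxon_adjacency_reported_but_not_shared(self):
        table = shared_derived_adjacencies(self.maps(), reference=set())
        row = table.loc["C.head--U.tail"]
        assert not row["shared"] and row["n_taxa"] == 1

    def test_reference_adjacencies_are_excluded(self):
        ref = {Adjacency.make(("U", "tail"), ("B", "head"))}
        table = shared_derived_adjacencies(self.maps(), reference=ref)
        assert "B.head--U.tail" not in table.index

    def test_matches_brute_force_set_algebra_on_random_maps(self):
        rng = np.random.default_rng(5)
        labels = list("ABCDEFGH")
        maps = {}
        for t in range(4):
            layout = {}
            for c in range(3):
                perm = rng.permutation(len(labels))[:4]
                layout[f"c{c}"] = [
                    (labels[j], 10 * k, 10 * k + 9, bool(rng.integers(2)))
                    for k, j in enumerate(perm)
                ]
            maps[f"t{t}"] = painted(layout)
        ref = extract_adjacencies(maps["t0"])  # arbitrary reference set
        table = shared_derived_adjacencies(maps, ref)
        per_taxon = {t: extract_adjacencies(m) for t, m in maps.items()}
        union = set().union(*per_taxon.values()) - ref
        assert set(table.index) == {str(a) for a in sorted(union)}
        for a in union:
            carriers = {t for t, s in per_taxon.items() if a in s}
            row = table.loc[str(a)]
            assert row["n_taxa"] == len(carriers)
            assert row["shared"] == (len(carriers) >= 2)

    def test_strict_mode_separates_different_block_borders(self):
        # same U-B extremity tokens, but breakpoints 200 ranks apart
        m1 = GBMap("g1", {"c1": [
            sub("U", 0, 9, ref_start=0, ref_end=9),
            sub("B", 10, 19, ref_start=100, ref_end=109),
        ]})
        m2 = GBMap("g2", {"c1": [
            sub("U", 0, 9, ref_start=200, ref_end=209),
            sub("B", 10, 19, ref_start=300, ref_end=309),
        ]})
        lenient = shared_derived_adjacencies({"a": m1, "b": m2}, set(), strict=False)
        strict = shared_derived_adjacencies({"a": m1, "b": m2}, set(), strict=True)
        key = "B.head--U.tail"
        assert bool(lenient.loc[key, "shared"])
        assert not bool(strict.loc[key, "shared"])


# ---------------------------------------------------------------------------
# parsimony


def unrooted_5_taxon_topologies():
    """All 15 unrooted binary topologies on 5 labeled leaves, as newick."""

    def insert_everywhere(node, label):
        variants = [(node, label)]
        if isinstance(node, tuple) and len(node) == 2:
            for i, child in enumerate(node):
                for v in insert_everywhere(child, label):
                    variants.append(tuple(v if j == i else node[j] for j in range(2)))
        return variants

    trees = [("A", "B", "C")]
    for label in ("D", "E"):
        nxt = []
        for t in trees:
            for i in range(3):
                for v in insert_everywhere(t[i], label):
                    nxt.append(tuple(v if j == i else t[j] for j in range(3)))
        trees = nxt

    def newick(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(newick(c) for c in node) + ")"

    return [newick(t) + ";" for t in trees]


def exhaustive_parsimony(tree, states):
    """Minimum changes by enumerating every internal (and missing-leaf)
    state assignment."""
    nodes = list(tree.preorder_node_iter())
    free = [
        nd
        for nd in nodes
        if not nd.is_leaf() or states[nd.taxon.label] == -1
    ]
    best = 10**9
    for assign in itertools.product((0, 1), repeat=len(free)):
        value = {}
        it = iter(assign)
        for nd in nodes:
            if nd in free:
                value[nd] = next(it)
            else:
                value[nd] = states[nd.taxon.label]
        cost = sum(
            1
            for nd in nodes
            if nd.parent_node is not None and value[nd] != value[nd.parent_node]
        )
        best = min(best, cost)
    return best


def read_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


class TestFitchScore:
    taxa = ["A", "B", "C", "D", "E"]

    def matrix(self, cells):
        cells = np.asarray(cells, dtype=np.int8)
        chars = [f"ch{j}" for j in range(cells.shape[1])]
        return CharacterMatrix(self.taxa, chars, cells)

    def test_all_zero_matrix_scores_zero_everywhere(self):
        m = self.matrix(np.zeros((5, 4), dtype=np.int8))
        for nwk in unrooted_5_taxon_topologies():
            assert fitch_score(read_tree(nwk), m) == 0

    def test_matches_exhaustive_enumeration_on_all_15_topologies(self):
        rng = np.random.default_rng(11)
        topologies = unrooted_5_taxon_topologies()
        assert len(topologies) == 15
        for trial in range(6):
            cells = rng.integers(0, 2, size=(5, 6)).astype(np.int8)
            if trial >= 4:  # sprinkle missing data
                cells[rng.integers(0, 5), rng.integers(0, 6)] = -1
            m = self.matrix(cells)
            for nwk in topologies:
                tree = read_tree(nwk)
                expected = sum(
                    exhaustive_parsimony(
                        tree, dict(zip(self.taxa, cells[:, j].tolist()))
                    )
                    for j in range(cells.shape[1])
                )
                assert fitch_score(tree, m) == expected

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(2)
        cells = rng.integers(0, 2, size=(5, 6)).astype(np.int8)
        m = self.matrix(cells)
        tree = read_tree("(A,(B,(C,(D,E))));")
        base = fitch_score(tree, m)
        for edge_i in (2, 4, 6):
            t2 = read_tree("(A,(B,(C,(D,E))));")
            edges = [e for e in t2.preorder_edge_iter() if e.head_node.parent_node]
            t2.reroot_at_edge(edges[edge_i % len(edges)])
            assert fitch_score(t2, m) == base

    def test_taxon_mismatch_lists_the_difference(self):
        m = self.matrix(np.zeros((5, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="Z"):
            fitch_score(read_tree("(A,(B,(C,(D,Z))));"), m)

    def test_aethionema_arabis_characters_favour_arabideae_early(self):
        cells = np.zeros((5, 3), dtype=np.int8)
        taxa = ["Aeth", "Arab", "LinIII", "LinI", "LinII"]
        cells[0, :] = cells[1, :] = 1  # shared by Aeth and Arab only
        m = CharacterMatrix(taxa, ["c1", "c2", "c3"], cells)
        early = read_tree("(Aeth,(Arab,(LinIII,(LinI,LinII))));")
        within = read_tree("(Aeth,(LinIII,(LinI,(LinII,Arab))));")
        assert fitch_score(early, m) <= fitch_score(within, m)


class TestRankTopologies:
    def test_orders_by_score_ascending(self):
        taxa = ["A", "B", "C", "D", "E"]
        cells = np.zeros((5, 2), dtype=np.int8)
        cells[0] = cells[1] = 1
        m = CharacterMatrix(taxa, ["c1", "c2"], cells)
        good = read_tree("((A,B),(C,(D,E)));")
        bad = read_tree("((A,C),(B,(D,E)));")
        ranking = rank_topologies(m, [bad, good])
        assert [t for t, _ in ranking] == [good, bad]
        assert ranking[0][1] < ranking[1][1]

    def test_identical_topologies_tie_in_input_order(self):
        taxa = ["A", "B", "C", "D", "E"]
        m = CharacterMatrix(taxa, ["c1"], np.ones((5, 1), dtype=np.int8))
        t1 = read_tree("(A,(B,(C,(D,E))));")
        t2 = read_tree("(A,(B,(C,(D,E))));")
        ranking = rank_topologies(m, [t1, t2])
        assert ranking[0][1] == ranking[1][1]
        assert ranking[0][0] is t1 and ranking[1][0] is t2
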