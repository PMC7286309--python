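"""Genomic-block adjacency characters and parsimony ranking of topologies.

Two sub-blocks lying contiguously on a chromosome define an adjacency
between their facing extremities (head = the ancestral-start side of a GB,
tail = its ancestral-end side; an inverted fragment presents them in
reverse).  Adjacencies present in two or more genomes but absent from the
ancestral karyotype are shared derived rearrangement characters; candidate
backbone topologies are ranked by their total small-parsimony change count
on those binary characters.

Two comparison modes are provided.  The lenient mode compares adjacencies
at GB-extremity resolution (fragment indices ignored).  The strict mode
additionally requires the reference-side breakpoint coordinates of the two
facing extremities to agree within a tolerance, which separates
convergent same-label associations with different block borders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .gb_projection import GBMap, SubBlock, UNASSIGNED
from .io_formats import GBDefinition

log = logging.getLogger(__name__)

__all__ = [
    "Adjacency",
    "AdjacencyObservation",
    "CharacterMatrix",
    "extract_adjacencies",
    "extract_adjacency_observations",
    "reference_adjacencies",
    "shared_derived_adjacencies",
    "build_character_matrix",
    "fitch_score",
    "rank_topologies",
    "read_topologies",
]

HEAD = "head"
TAIL = "tail"


@dataclass(frozen=True, order=True)
class Adjacency:
    """An unordered pair of block extremities, normalised lexicographically."""

    endpoint_1: tuple[str, str]  # (gb_label, head|tail)
    endpoint_2: tuple[str, str]

    @classmethod
    def make(cls, e1: tuple[str, str], e2: tuple[str, str]) -> "Adjacency":
        a, b = sorted((e1, e2))
        return cls(a, b)

    def __str__(self) -> str:
        return f"{self.endpoint_1[0]}.{self.endpoint_1[1]}--{self.endpoint_2[0]}.{self.endpoint_2[1]}"


@dataclass(frozen=True)
class AdjacencyObservation:
    """One observed adjacency with the reference-side breakpoint coordinate
    (reference gene rank) of each facing extremity."""

    adjacency: Adjacency
    ref_break_1: int
    ref_break_2: int


def _facing_ends(sb: SubBlock) -> tuple[tuple[str, str], tuple[str, str]]:
    """(left, right) extremity tokens of a sub-block as laid on the query."""
    if sb.inverted:
        return (sb.gb_label, TAIL), (sb.gb_label, HEAD)
    return (sb.gb_label, HEAD), (sb.gb_label, TAIL)


def _end_ref_coord(sb: SubBlock, end: str) -> int:
    return sb.ref_start if end == HEAD else sb.ref_end


def extract_adjacency_observations(
    gb_map: GBMap, max_gap_genes: int = 50
) -> list[AdjacencyObservation]:
    obs: list[AdjacencyObservation] = []
    for subs in gb_map.chromosomes.values():
        for prev, cur in zip(subs, subs[1:]):
            gap = cur.rank_start - prev.rank_end - 1
            if gap > max_gap_genes:
                continue
            if prev.gb_label == UNASSIGNED or cur.gb_label == UNASSIGNED:
                continue
            right = _facing_ends(prev)[1]
            left = _facing_ends(cur)[0]
            obs.append(
                AdjacencyObservation(
                    Adjacency.make(right, left),
                    _end_ref_coord(prev, right[1]),
                    _end_ref_coord(cur, left[1]),
                )
            )
    return obs


def extract_adjacencies(gb_map: GBMap, max_gap_genes: int = 50) -> set[Adjacency]:
    """Adjacency set of a painted karyotype: one adjacency per pair of
    consecutive sub-blocks separated by at most ``max_gap_genes`` unassigned
    genes, joining the facing extremities (inversion flags respected)."""
    return {o.adjacency for o in extract_adjacency_observations(gb_map, max_gap_genes)}


def reference_adjacencies(gb_table: list[GBDefinition]) -> set[Adjacency]:
    """Adjacencies of the ancestral karyotype itself: consecutive GB pairs
    within each ancestral chromosome, in table order."""
    by_chrom: dict[str, list[GBDefinition]] = {}
    for d in gb_table:
        by_chrom.setdefault(d.ak_chrom, []).append(d)
    out: set[Adjacency] = set()
    for defs in by_chrom.values():
        for prev, cur in zip(defs, defs[1:]):
            out.add(Adjacency.make((prev.label, TAIL), (cur.label, HEAD)))
    return out


def shared_derived_adjacencies(
    maps: dict[str, GBMap],
    reference: set[Adjacency],
    max_gap_genes: int = 50,
    strict: bool = False,
    strict_tol: int = 50,
) -> pd.DataFrame:
    """Tabulate adjacencies absent from the reference karyotype across taxa.

    Returns a DataFrame indexed by adjacency, one boolean column per taxon,
    plus ``n_taxa`` and ``shared`` (present in >= 2 taxa).  In strict mode
    an adjacency only counts as shared when some pair of carrying taxa
    agrees on both reference-side breakpoint coordinates within
    ``strict_tol`` gene ranks ("different block borders" then separate
    convergent associations).
    """
    if len(maps) < 2:
        raise ValueError("shared_derived_adjacencies needs at least two maps")
    observations = {
        taxon: extract_adjacency_observations(m, max_gap_genes)
        for taxon, m in sorted(maps.items())
    }
    taxa = sorted(maps)
    all_adj = sorted(
        {o.adjacency for obs in observations.values() for o in obs} - reference
    )
    rows = []
    for adj in all_adj:
        present = {
            taxon: any(o.adjacency == adj for o in obs)
            for taxon, obs in observations.items()
        }
        n = sum(present.values())
        shared = n >= 2
        if shared and strict:
            carriers = [t for t in taxa if present[t]]
            shared = False
            for i, t1 in enumerate(carriers):
                o1s = [o for o in observations[t1] if o.adjacency == adj]
                for t2 in carriers[i + 1 :]:
                    o2s = [o for o in observations[t2] if o.adjacency == adj]
                    if any(
                        abs(a.ref_break_1 - b.ref_break_1) <= strict_tol
                        and abs(a.ref_break_2 - b.ref_break_2) <= strict_tol
                        for a in o1s
                        for b in o2s
                    ):
                        shared = True
                        break
                if shared:
                    break
        rows.append({**present, "n_taxa": n, "shared": shared})
    return pd.DataFrame(rows, index=[str(a) for a in all_adj], columns=taxa + ["n_taxa", "shared"])


# ---------------------------------------------------------------------------
# parsimony


@dataclass
class CharacterMatrix:
    """Binary presence matrix: taxa x adjacency characters.

    Cells are 1 (present), 0 (absent) or -1 (missing, scored as free)."""

    taxa: list[str]
    characters: list[str]
    cells: np.ndarray  # shape (len(taxa), len(characters)), int8

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("matrix shape does not match taxa/characters")

    def column(self, j: int) -> dict[str, int]:
        return {t: int(self.cells[i, j]) for i, t in enumerate(self.taxa)}


def build_character_matrix(
    presence: pd.DataFrame, taxa: list[str] | None = None, shared_only: bool = True
) -> CharacterMatrix:
    """Build a binary matrix from a shared-derived adjacency table."""
    df = presence[presence["shared"]] if shared_only else presence
    if taxa is None:
        taxa = [c for c in presence.columns if c not in ("n_taxa", "shared")]
    cells = np.array([[1 if df.iloc[j][t] else 0 for j in range(len(df))] for t in taxa], dtype=np.int8)
    if len(df) == 0:
        cells = np.zeros((len(taxa), 0), dtype=np.int8)
    return CharacterMatrix(list(taxa), list(df.index), cells)


def read_topologies(path) -> list[dendropy.Tree]:
    return list(
        dendropy.TreeList.get(path=str(path), schema="newick", preserve_underscores=True)
    )


def fitch_score(tree: dendropy.Tree, matrix: CharacterMatrix) -> int:
    """Minimum number of state changes of all characters on the topology.

    Computed by unit-cost dynamic programming over binary states (exact on
    bifurcating and multifurcating trees alike; equals the Fitch count on
    binary trees).  Missing cells (-1) constrain nothing.  Invariant under
    re-rooting.
    """
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taxa = set(matrix.taxa)
    if leaf_labels != taxa:
        raise ValueError(
            "taxon sets differ: tree-only="
            f"{sorted(leaf_labels - taxa)}, matrix-only={sorted(taxa - leaf_labels)}"
        )
    idx = {t: i for i, t in enumerate(matrix.taxa)}
    INF = 1 << 30
    total = 0
    for j in range(len(matrix.characters)):
        costs: dict[int, tuple[int, int]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                s = int(matrix.cells[idx[node.taxon.label], j])
                if s == -1:
                    costs[id(node)] = (0, 0)
                else:
                    costs[id(node)] = (0, INF) if s == 0 else (INF, 0)
            else:
                c0 = c1 = 0
                for child in node.child_nodes():
                    k0, k1 = costs[id(child)]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k1, k0 + 1)
                costs[id(node)] = (c0, c1)
        total += min(costs[id(tree.seed_node)])
    return total


def rank_topologies(
    matrix: CharacterMatrix, topologies: list[dendropy.Tree]
) -> list[tuple[dendropy.Tree, int]]:
    """Score and order candidate topologies, most parsimonious first.

    Ties keep input order (reported as equal scores)."""
    if len(topologies) < 2:
        raise ValueError("rank_topologies needs at least two topologies")
    scored = [(t, fitch_score(t, matrix)) for t in topologies]
    return sorted(scored, key=lambda ts: ts[1])
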