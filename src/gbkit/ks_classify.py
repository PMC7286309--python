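"""Ks-based discrimination of orthologous vs WGD-derived syntenic blocks.

Between two post-polyploid crucifer genomes every region of one genome is
syntenic both to its ortholog and to the At-alpha homeolog of that ortholog
in the other genome.  The two kinds of block separate on the synonymous
substitution rate Ks: ortholog pairs diverged at speciation, paralog pairs
at the older whole-genome duplication, so paralog Ks sits in a higher mode.
Only Ks < ks_max (default 2) is treated as approximately linear with time
and used for fitting.

Mode estimation fits a two-component Gaussian mixture to log Ks (a log-
normal mixture on the Ks scale); each component mode is exp(mu - sigma^2)
and the classification cut is the density minimum of the fitted mixture
between the two modes.  Classification itself uses the per-block *median*
Ks, which is robust to stray paralog anchors inside an ortholog block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import mean, median

import numpy as np

from .chaining import Origin, SyntenicBlock

log = logging.getLogger(__name__)

__all__ = [
    "KsModes",
    "block_median_ks",
    "block_mean_ks",
    "estimate_ks_modes",
    "classify_blocks",
    "deduplicate_blocks",
]


@dataclass
class KsModes:
    """Estimated ortholog / WGD Ks modes and the classification boundary.

    ``cut`` is None when the Ks distribution is effectively unimodal; the
    caller must then supply a manual cut (or treat everything as ortholog
    when no WGD signal is expected)."""

    ortholog_mode: float
    wgd_mode: float | None
    cut: float | None
    ks_max: float = 2.0

    @property
    def unimodal(self) -> bool:
        return self.cut is None


def _usable_ks(block: SyntenicBlock, ks_max: float) -> list[float]:
    return [
        pa.pair.ks
        for pa in block.anchors
        if pa.pair.ks is not None and pa.pair.ks < ks_max
    ]


def block_median_ks(block: SyntenicBlock, ks_max: float = 2.0) -> float | None:
    """Median Ks over the block's anchors with usable Ks; None if no anchor
    has a usable value."""
    vals = _usable_ks(block, ks_max)
    return median(vals) if vals else None


def block_mean_ks(block: SyntenicBlock, ks_max: float = 2.0) -> float | None:
    vals = _usable_ks(block, ks_max)
    return mean(vals) if vals else None


def estimate_ks_modes(
    anchors,
    ks_max: float = 2.0,
    min_separation: float = 0.05,
    grid_points: int = 512,
    random_state: int = 0,
) -> KsModes:
    """Estimate the ortholog and WGD Ks modes from anchor pairs.

    Fits a two-component Gaussian mixture to log Ks restricted to
    (0, ks_max).  If the fitted components collapse onto one another, or the
    mixture density has no interior minimum between the two modes, the
    distribution is reported unimodal with an undefined cut.

    Requires at least 100 usable Ks values.
    """
    from sklearn.mixture import GaussianMixture

    values = np.asarray(
        [p.ks for p in anchors if p.ks is not None and 0 < p.ks < ks_max], dtype=float
    )
    if values.size < 100:
        raise ValueError(
            f"mode estimation needs >= 100 usable Ks values, got {values.size}"
        )
    if np.ptp(values) == 0:
        return KsModes(float(values[0]), None, None, ks_max)
    y = np.log(values).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=3, random_state=random_state).fit(y)
    mu = gm.means_.ravel()
    var = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    modes = np.exp(mu - var)  # mode of each log-normal component
    order = np.argsort(modes)
    m_lo, m_hi = float(modes[order[0]]), float(modes[order[1]])
    if m_hi - m_lo < min_separation or min(weights) < 1e-3:
        log.info("Ks distribution unimodal (modes %.3f / %.3f)", m_lo, m_hi)
        mode = float(modes[order[np.argmax(weights[order])]])
        return KsModes(mode, None, None, ks_max)
    # density minimum of the fitted mixture between the two modes
    xs = np.linspace(m_lo, m_hi, grid_points)
    dens = np.zeros_like(xs)
    for w, m, v in zip(weights, mu, var):
        sd = np.sqrt(v)
        dens += (
            w
            * np.exp(-((np.log(xs) - m) ** 2) / (2 * v))
            / (xs * sd * np.sqrt(2 * np.pi))
        )
    imin = int(np.argmin(dens[1:-1])) + 1
    if dens[imin] >= min(dens[0], dens[-1]):
        return KsModes(m_lo if weights[order[0]] >= weights[order[1]] else m_hi, None, None, ks_max)
    cut = float(xs[imin])
    return KsModes(m_lo, m_hi, cut, ks_max)


def classify_blocks(blocks, modes: KsModes) -> list[SyntenicBlock]:
    """Assign each block an origin from its median Ks.

    median < cut        -> ORTHOLOG
    cut <= median < max -> WGD_PARALOG (excluded from projection; the
                           boundary itself is assigned to the paralog side)
    no usable Ks        -> UNCLASSIFIED (retained, logged)
    """
    if modes.cut is None:
        raise ValueError(
            "classification cut undefined (unimodal Ks); supply a manual cut"
        )
    n_unclassified = 0
    for b in blocks:
        b.median_ks = block_median_ks(b, modes.ks_max)
        b.mean_ks = block_mean_ks(b, modes.ks_max)
        if b.median_ks is None:
            b.origin = Origin.UNCLASSIFIED
            n_unclassified += 1
        elif b.median_ks < modes.cut:
            b.origin = Origin.ORTHOLOG
        else:
            b.origin = Origin.WGD_PARALOG
    if n_unclassified:
        log.info("%d blocks without usable Ks left UNCLASSIFIED", n_unclassified)
    return blocks


def deduplicate_blocks(blocks, overlap_frac: float = 0.5) -> list[SyntenicBlock]:
    """Resolve redundant coverage of the same part of the reference.

    Among ORTHOLOG blocks that cover the same reference genes -- at least
    ``overlap_frac`` of the smaller block's anchored reference ranks -- only
    the block with the lowest median Ks keeps its status; the others are
    re-marked DISCARDED.  Overlap is measured on the anchored reference
    ranks themselves rather than on raw spans, so a block nested inside the
    *gap* of another (an inverted fragment between its flanks) is not
    mistaken for a redundant copy.  The greedy sweep in ascending median-Ks
    order equals the closure of the pairwise lower-Ks-wins rule and is
    independent of input order.
    """
    ortho = [b for b in blocks if b.origin == Origin.ORTHOLOG]
    ortho.sort(key=lambda b: (b.median_ks if b.median_ks is not None else np.inf, b.block_id))
    kept: list[tuple[SyntenicBlock, set[int]]] = []
    for b in ortho:
        ranks = {pa.rank_b for pa in b.anchors}
        clash = False
        for k, kranks in kept:
            if k.chrom_b != b.chrom_b:
                continue
            if len(ranks & kranks) >= overlap_frac * min(len(ranks), len(kranks)):
                clash = True
                break
        if clash:
            b.origin = Origin.DISCARDED
            b.note = (b.note + " " if b.note else "") + "redundant:higher-ks"
        else:
            kept.append((b, ranks))
    return blocks
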