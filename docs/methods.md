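# Methods

`gbkit` reimplements, as a tested pipeline over synthetic genomes, the
comparative-genomics workflow used to paint crucifer genomes with the
ancestral genomic blocks (GBs) of the Ancestral Crucifer Karyotype (ACK)
and to mine shared block adjacencies as phylogenetic characters.  This
note records the models, the defaults and why they are what they are, what
the simulator does and does not emulate, and the numerical choices made
where the design was open.

## Synteny chaining in gene-rank space

Anchors (homologous gene pairs) are points `(rank_a, rank_b)` in the
rank coordinates of a query and a reference chromosome; gene rank, not bp,
is the distance unit throughout, matching the relative-gene-order mode of
SynMap/DAGchainer-style tools.  A chain is a run of anchors strictly
increasing in `rank_a` and strictly monotone in `rank_b`, with consecutive
anchors at most `max_gap` ranks apart in both genomes.  Chains are scored

    score = sum(anchor scores) - gap_penalty * sum(max(da, db) - 1)

with a default anchor score of 1 (no homology-score weighting — upstream
aligner scores carry little information once pairs are accepted as
anchors) and `gap_penalty = 0.2` per skipped rank, so a maximal 25-rank
jump costs ~5, far below the 20-pair block floor: gaps shape chain choice
but never outweigh real anchors.  Extraction is greedy best-first
(DAGchainer behaviour): dynamic programming finds the maximum-score chain,
its anchors are removed, and the search repeats; ties break toward the
lexicographically smallest chain start for determinism.  Antisense chains
come from negating `rank_b` and re-running the same DP.  Defaults
`max_gap = 25` and `min_pairs = 20` are the genomic-block detection
settings of the study this package reproduces; the pair floor is applied
*after* extraction, so raising it can only remove blocks (a tested
monotonicity invariant).

Nearby same-orientation blocks merge, QuotaAlign-style, when the rank gap
between their spans is at most `merge_dist = 50` on both genomes and the
union is still monotone — with one additional guard: a merge is refused
when a third block lies in the gap being bridged.  Without the guard the
flanks of an inversion (or of an inserted translocated segment) merge
across it and the resulting block's span swallows the inner fragment
during projection; with it, inverted sub-blocks survive painting, as they
must.  `manual_merge` remains for same-GB fragments farther apart than the
merge distance.

## Ks classification

Between two post-WGD genomes every query region is syntenic both to its
ortholog and to the At-alpha homeolog of that ortholog, and the two
separate on the synonymous substitution rate Ks: ortholog pairs diverged
at speciation, paralog pairs at the older duplication.  Only `Ks < 2` is
used (approximately linear with time; larger values are kept in the data
but never fitted).

Mode estimation fits a two-component Gaussian mixture to `log Ks` — a
log-normal mixture on the Ks scale, which is also the simulator's
generative model.  Component modes are `exp(mu - sigma^2)` and the
classification cut is the density minimum of the fitted mixture between
the two modes.  A kernel-density peak finder was evaluated first and
rejected: with Silverman bandwidth it fails to resolve modes at 0.77/1.37
(log-sd 0.2) in roughly a third of samples, because the true mixture
density's upper peak already sits at 1.34 and smoothing flattens the
valley; the mixture fit recovers both planted modes to within ~0.02.
When the fitted components collapse, or no interior density minimum
exists, the distribution is reported unimodal with an undefined cut; the
pipeline then either takes a manual cut or — when no WGD signal is
expected, as in rearrangement-only simulations — treats every block with
usable Ks as orthologous, with a logged warning.

Blocks are classified on their **median** anchor Ks (robust to stray
paralog anchors; the mean is reported alongside).  A median exactly at the
cut goes to the paralog side — conservative for projection, since a
wrongly kept paralog block paints spurious sub-blocks while a wrongly
dropped ortholog block merely leaves a gap.

Redundant coverage of the same reference region (two surviving blocks
covering the same ACK interval) keeps the lower-median-Ks block.  "Same
part" means the anchored reference ranks intersect by at least half of the
smaller block's anchors; anchored ranks rather than raw spans, because a
span can contain another block inside a bridged gap without sharing a
single reference gene with it.  The greedy sweep in ascending median-Ks
order equals the closure of the pairwise lower-Ks-wins rule and is
independent of input order.

## Projection onto the genomic blocks

Each ortholog block is split at every GB interval boundary its reference
span crosses; fragments below `min_subblock = 20` anchors are dropped
unless their GB is in the allow-small set (default `{G}`, the published
six-gene exception for block G — an exception about the real Aethionema
assembly, and deliberately switched off in synthetic-recovery scenarios).
A fragment is inverted when its anchors run antiparallel to its GB's
reference direction; the call is the sign of the Spearman correlation of
query vs reference anchor ranks, with |rho| < 0.5 reported ambiguous and
not inverted (within a single chained block |rho| is exactly 1; the
ambiguity path guards manually merged blocks).

Map assembly gives every query gene to at most one fragment:

1. fragments are admitted largest-first with per-gene exclusivity
   (one-to-many homologs resolve to the larger fragment);
2. when two admitted fragments' spans overlap and both have anchors in the
   shared interval, the fragment with fewer anchors there forfeits them —
   this strips the occasional "stepping-stone" anchor a chain picks up
   while bridging across an inverted segment, without letting that single
   anchor shatter the genuine fragment underneath;
3. every fragment is then split wherever another fragment's surviving
   anchors interleave between its consecutive anchors, and the pieces must
   re-pass the size floor.

Fragments of each GB are finally numbered 1..k by their reference start
positions (ordered relative to the ACK), and maps are sorted per query
chromosome.

## Adjacency characters and parsimony

Two consecutive sub-blocks separated by at most 50 unassigned genes (the
merge distance, reused) define an adjacency between their facing
extremities: `head` is a GB's ancestral-start side, `tail` its end, and an
inverted fragment presents them reversed.  Characters compare at
GB-extremity resolution (fragment indices ignored); a strict mode
additionally requires the reference-side breakpoint coordinates of both
extremities to agree between genomes within 50 ranks, separating
convergent same-label associations that arose from different breaks.
Adjacencies present in two or more genomes but absent from the reference
karyotype (whose own adjacency set is the consecutive GB pairs of each
ancestral chromosome) are the shared derived characters.

Topologies are scored by minimum-change parsimony on the binary presence
characters, computed by unit-cost dynamic programming over states — exact
on bifurcating and multifurcating trees alike, equal to the Fitch count on
binary trees, invariant under re-rooting (tested), with missing cells
("?", e.g. unassembled regions) contributing no constraint.  Only supplied
topologies are scored; there is no tree search.

## The simulator

The generator builds an ancestral karyotype — by default 8 chromosomes
carrying 22 GBs (3,3,3,3,3,3,2,2) of 100 genes each, the ACK-like layout —
and evolves it along a newick tree whose branch lengths are expressed
directly in Ks units.  Per branch, in order: an optional WGD (every
chromosome duplicated; by default placed on the root edge, shared by all
taxa), biased fractionation (each still-duplicated gene loses one copy
with probability `loss_prob`; the lost copy is the subgenome-1 copy with
probability `copy_bias`), then rearrangements — inversions (reverse a
uniform rank interval, flipping strand), translocations (move a uniform
segment to a uniform position), fissions and fusions — either sampled
counts or explicitly planted events with fixed breakpoints.  All
randomness derives from one seed through per-branch and per-table
substreams keyed by stable name hashes; a fixed seed reproduces the output
byte for byte (tested).

Anchor Ks is log-normal with the mode at the pair's patristic distance,
plus a WGD excess (`wgd.ks_mode`, default 0.6) for pairs that diverged at
the duplication; log-sd 0.2.  The emitted reference genome is the
ancestral arrangement itself, modelled as an extant reference lineage
hanging off the root (`ref_branch_ks = 0.40`) that retained subgenome 1 —
so subgenome-1 query copies are its orthologs and subgenome-2 copies its
paralogs.  The default tree places the Aethionema analog at depth 0.37,
giving ortholog/paralog Ks modes of 0.77 and 1.37 against the reference —
the values reported for the real Aethionema–Arabidopsis comparison — and
crown-lineage tip-tip modes of ~0.3–0.5.  The *study configuration*
(`simulate.study_config`) adds the WGD, fractionation with
`loss_prob = 0.35` and `copy_bias = 0.65` (orthologous copies depleted, so
paralog blocks carry more syntenic genes, the direction observed in real
data; the rate itself is a free parameter — no quantitative fractionation
rate is published for Brassicaceae), and five inversions, two
translocations, one fission and one fusion per branch.

Ground truth includes per-taxon painted maps obtained by segmenting each
chromosome into maximal runs of constant GB label whose ancestral ranks
advance monotonically with steps and query gaps at most 50.  Runs break on
rank-direction change, not on strand alone: a single-gene strand flip is
invisible to any rank-space detector, so it is no boundary.  For
comparison with the pipeline, truth is also produced *at analysis
resolution*: runs under 20 genes removed and compatible neighbours
re-collapsed — what an ideal detector with the pipeline's floor and merge
distance could possibly report.

What the simulator does **not** emulate: nucleotide sequences (Ks is
drawn, not computed), rate heterogeneity across genes beyond the log-sd,
breakpoint reuse (a uniform model; the knob for reuse bias is the obvious
extension), tandem duplications, nested mesopolyploidy, and assembly
artefacts.  Passing tests therefore demonstrate that the *pipeline logic*
is correct under the stated generative model, not that the thresholds are
optimal for any particular real assembly.

## Problem sizes and determinism

The test battery and the acceptance script run the 22-block, 2,200-gene
ancestor with five taxa (about 3,000 anchors per taxon pair after WGD and
fractionation); a full simulate-plus-pipeline pass takes a few seconds.
The chain DP is windowed on `rank_a` (candidates within `max_gap`), so
chaining is near-linear on collinear data.  Every stochastic step is
seeded; the pipeline is a pure function of (inputs, config, seed), tested
by byte-identical reruns.

## Known limitations

* When a translocation displaces a segment smaller than the sub-block
  floor, the anchors sometimes admit two valid tilings (bridge the splice
  and drop the displaced snippet, or break at it); the detector's greedy
  choice can then differ from the truth segmentation by one boundary.  In
  20 random 13-event scenarios this affected 2, each by a single boundary
  or adjacency.
* The Ks mixture assumes exactly two components; blocks from older
  duplications (At-beta-like) would fall into the WGD class rather than a
  third one.
* Presence coding treats adjacency loss and non-assembly identically
  unless cells are explicitly down-coded to missing.
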