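# Methods

This note documents the models, conventions and design choices behind
`genefam`, in the order the pipeline runs them.

## Gene models and intron extraction

GFF3 input is 1-based closed per the format; all internal coordinates are
0-based half-open, converted once at the parsing boundary. One gene model is
built per mRNA from its CDS features; minus-strand exons are
reverse-complemented and ordered 5'→3' along the transcript. Alternative
transcripts of a gene are collapsed to the longest CDS by default (the
analysis counts one transcript per locus; collapsing can be disabled).
The terminal stop codon is excluded from the reported protein. Models whose
CDS length is not a multiple of three are flagged `incomplete` and excluded
from phase analysis by default, since a frameshifted offset would make the
phase classification meaningless.

Introns are the gaps between consecutive exons in transcription order; the
donor and acceptor are the first and last two intron nucleotides on the
transcribed strand. Splice junctions are taken from the annotation and then
*validated* against the GT/AG rule — non-canonical introns (e.g. GC donors)
are retained and flagged rather than dropped, because a non-canonical site
in a curated gene model is a data point, not an error. Introns shorter than
4 nt (no room for donor + acceptor) are rejected.

## Alignment

External protein alignments are first-class input, since real analyses of
this kind use a dedicated aligner. The built-in progressive aligner exists
so the pipeline and its tests have no external dependency: global affine-gap
(Gotoh) dynamic programming, BLOSUM62, gap open −10 / extend −0.5 (the
first gap character costs the open penalty), guide tree from neighbor
joining on 3-mer distances, profiles merged in postorder with
average-of-pairs column scores. Traceback ties break diagonal → up → left,
so output is deterministic. The pairwise scores are verified in the test
suite against both exhaustive enumeration of all global alignments (tiny
sequences) and Biopython's independent `PairwiseAligner`.

## Intron projection and conserved sites

The canonical site coordinate is the nucleotide position in a
codon-expanded alignment, `aln_nt_pos = 3(column−1) + phase`, anchored to
the residue whose codon hosts (phase 1/2) or immediately follows (phase 0)
the splice. This convention makes `aln_nt_pos mod 3 == phase` an invariant
and is self-consistent across genes aligned to the same frame; published
figures of this kind print positions under unstated conventions, so no
attempt is made to reproduce any particular printed coordinate. An intron
whose splice falls after the final codon has no hosting residue and is
excluded with a warning.

Conserved sites are found by single-linkage chaining of same-phase sites
within a position tolerance of 3 nt (one codon of alignment jitter — the
motivating observation is a shared phase-0 intron reported at two adjacent
alignment positions in different genes). Single linkage avoids fixed-bin
boundary artifacts and is order-independent after sorting. A gene
contributes at most one site per group; when chaining would pull in two
introns of one gene, the site closer to the group median is kept (ties to
the lower ordinal). Groups need ≥ 2 distinct genes.

Intron length statistics report count, intronless-gene count, arithmetic
mean (rounded only for display), extremes, and a fixed-width histogram
(500 nt bins from zero).

## JTT distances and trees

The JTT replacement model is built from the published Jones–Taylor–Thornton
(1992) exchangeabilities and equilibrium frequencies (the canonical
`jones.dat` integer matrix): `Q_ij = S_ij π_j`, normalised to one expected
substitution per site per unit time, so distances are in substitutions per
site. `P(t) = exp(Qt)` is computed once per evaluation from the symmetric
eigendecomposition. The pairwise distance is the maximum-likelihood scalar
`t` over shared-residue columns (pairwise gap deletion), found by bounded
Brent search on (0, 10] with tolerance 1e-6; identical rows short-circuit to
0. Pairs whose likelihood is still rising at the bound are capped at 10 and
flagged with a `SaturationWarning` — saturated distances are reported, not
repaired. The test suite cross-checks the distances against phangorn's
independent `dist.ml(model="JTT")` implementation.

Neighbor joining is the standard Saitou–Nei algorithm with deterministic
tie-breaking (smallest index pair). Negative branch-length estimates are
clamped to zero with the deficit moved to the adjacent branch of the same
join, preserving path lengths. Minimum-evolution refinement is an NNI hill
climb over internal edges minimising the sum of OLS branch-length estimates
(Rzhetsky–Nei criterion); the input tree is returned unchanged when no
interchange improves it — on additive matrices NJ is already optimal, which
the tests verify. No rate heterogeneity across sites is modelled.

Bootstrap support is the percentage of column-resampled replicates (default
500, the conventional setting) whose NJ tree contains the same leaf
bipartition, from a single seeded RNG stream. Internal edges of length
≤ 1e-12 in a replicate are treated as unresolved polytomy edges and not
counted; this makes an alignment of identical sequences report support 0
everywhere instead of an artifact of deterministic tie-breaking.
Bipartitions are normalised to the smaller side (ties to the side holding
the alphabetically first leaf), and clades flagged above the support
threshold (default 50%) are these normalised leaf sets.

## Chromosome map and microsynteny

Two family loci chain into a cluster when at most `max_interlopers = 1`
non-family genes lie between them, matching the observed pattern of tandem
esterase clusters that tolerate a single unrelated insertion; when the
input carries no non-family annotation at all the criterion falls back to a
genomic gap ≤ 100 kb. Clusters are maximal chains with ≥ 2 members;
orientation patterns record member strands in positional order. A cluster
is concordant with the phylogeny when its members are contained in some
flagged clade. Distance to the chromosome end is reported only as a
fraction of the half-chromosome (no telomere/centromere call — assembly
landmarks are not part of the input).

Microsynteny events are a direct partition comparison, not a minimal
rearrangement solver. Copy-number differences give duplication/loss. For
shared groups, the chromosome co-membership partition of species A is
compared with that of B: an A block scattered over k ≥ 2 B chromosomes
yields k−1 split events (each separated part relative to the largest), and
a B chromosome hosting blocks from m ≥ 2 A chromosomes yields one fusion
event covering its groups — so splits of (A,B) correspond to fusions of
(B,A). A group is conserved when its block is identical in both species
and its copy number unchanged. Groups on multiple chromosomes within one
species are tagged ambiguous in the event detail.

## EST expression

Tabulation is purely descriptive: clone counts per gene × tissue with zero
rows retained, a per-gene clone-count frequency distribution, and a
per-tissue summary sorted by clone count. The frequency bins are singleton
counts 0–14 plus an open ">15" bin; there is no separate bin for exactly
15, so a count of 15 falls into the open bin (this mirrors the bin layout
of the published table the fixture transcribes, which likewise lists no
15 bin). Library depths are unknown, so counts are never normalised.
The clade × tissue Fisher-exact/Benjamini–Hochberg enrichment layer is an
extension beyond the descriptive tables and is off by default.

The two packaged TSVs under `genefam/data/` are verbatim transcriptions of
published EST summary tables (clone-count bins; tissue counts) used as
worked-example fixtures; their internal consistency (69 genes, 47 with ≥ 1
clone, 354 clones, midgut 23 genes / 104 clones) is asserted in the tests.

## Synthetic families

The generator is the package's test bed and defines its study conditions.
A Yule tree with the requested number of leaves is scaled so the
root-to-tip path equals `branch_scale` (default 0.3 substitutions/site).
The ancestral protein is drawn from JTT equilibrium frequencies; sequences
evolve by per-site substitution with `P(t)` per branch. Indels insert or
delete whole residues (codon-aligned), so residue homology — tracked with
rational-number site keys whose sort order is the true alignment — remains
well defined without frameshift bookkeeping; the initiator residue is never
deleted. Ancestral introns are anchored to residues ≥ 3 residues apart
(≥ 9 nt in the codon frame, so same-phase truth groups can never merge at
the 3 nt tolerance); each surviving intron faces an explicit Bernoulli loss
trial per branch, and deletion of the anchor residue removes the intron
outright. Gains are Poisson per branch at uniform internal offsets, ≥ 2
residues from existing introns.

Defaults emulate a ~70-member esterase family: 69 genes, 6 ancestral
introns, loss 0.15/branch, intron lengths 68 + Exp(mean−68) nt clipped to
[68, 13962] (mean 1372 nt — the long right tail of real intron lengths),
5% non-canonical splice sites, tandem clusters of six (one interloper) and
four genes, 16 tissue libraries with symmetric-Dirichlet tissue biases
(concentration 0.4) and negative-binomial clone counts (mean 5.1,
dispersion 0.45, giving ≈ 30% zero-clone genes as in sparse EST
collections). Test and acceptance runs use smaller families (12–50 genes,
100–300 residues) to keep runtimes in seconds; the statistical checks are
scale-free. What the generator does *not* emulate: base composition and
codon usage of any real genome, splice-site motifs beyond the terminal
dinucleotides, global tissue skew shared across genes (each gene draws its
own tissue profile), and alignment-guide-tree error on real divergent
families — so passing tests demonstrate correctness of the machinery, not
robustness to every property of real data.

Each simulated family emits genome FASTA, GFF3, EST TSV, a loci table, a
self ortholog map and a JSON truth set (true tree, true alignment,
surviving introns with offsets and splice flags, loss-trial tallies,
cluster memberships, expected expression counts). Outputs are
byte-identical for identical seed and configuration; one RNG stream is
consumed in a fixed documented order (tree, sequences/introns, gene
emission, layout, expression).

Two statistical conventions in the tests deserve note. Per-gene survival
indicators of one ancestral intron are correlated through shared branches,
so "survivor counts are binomial" is not exact; instead the tests check
the quantity that *is* exactly binomial — pooled per-branch loss events
given the number of trials — against the 99% binomial band, plus exact
equality of recovered group memberships with the generator truth. And the
conserved-site recovery scenario sets `indel_prob = 0` so that intron loss
is the only process acting (with indels on, anchor deletion is an
additional loss channel and exact 50/50 membership is not the true
expectation); with no indels the progressive aligner provably returns the
ungapped stack, so the check runs end-to-end from FASTA/GFF3 through the
package's own aligner.

## Pipeline

`genefam all` executes genome → introns → alignment → {conserved sites,
phylogeny} → clusters → synteny → expression, writing per-stage TSV/JSON,
a newick tree with supports, a run log and a consolidated `report.json`
that echoes the resolved parameters and tallies warnings (non-canonical
sites, incomplete models, saturated distances, unprojectable introns).
Stage failures abort with the stage name. Reports are pure functions of
inputs plus configuration; rerunning with the same seed reproduces the
report exactly.

## Known limitations

- The ME search is a plain NNI hill climb; it can stop in a local optimum
  that a deeper rearrangement search would escape. Topology identity with
  any particular external implementation is therefore not guaranteed and
  not asserted.
- The progressive aligner is a baseline (no iterative refinement); on
  divergent indel-rich families its column assignments can split a true
  conserved-intron group across adjacent positions.
- Synteny inference compares partitions directly and does not search for a
  minimal event history; nested or overlapping rearrangements can be
  reported as multiple elementary events.
- EST counts are used as-is; without library sizes no statement about
  relative expression level between tissues is made.
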