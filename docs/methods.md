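# Methods

## Coordinates and the definition of an intron position

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the parsing boundary.  The CDS is taken to
*include* the stop codon (the GFF3 convention), so a CDS of length 3(L+1)
encodes a protein of L residues, and an intron anchored within or after the
stop codon is a projection error rather than a silent off-by-one.

An intron is identified by *p*, the number of coding nucleotides strictly
5′ of it.  Phase is *p* mod 3; the anchor residue is codon ⌊*p*/3⌋ for all
phases, so a phase-0 intron is anchored on the residue that *follows* it.
This single rule keeps phase-0/1/2 introns of one codon on one alignment
column, which is what makes column-and-phase identity a usable homology
criterion.  Exons encoding species-specific amino-terminal extensions must
be trimmed by the caller before input; the tool does not guess which exons
are lineage-specific.

## Position homology, near matches, convergence

Homology of intron positions is exact: same alignment column, same phase.
Nearby-but-distinct positions are never merged, because offsets of a few
nucleotides (7 bp, 23 bp in the motivating data) are exactly the signal
that distinguishes independent insertions from shared ones.  Near matches
and cross-family convergence reports measure offsets on one declared
reference row's coding axis (3·r + phase, r = reference residues before
the column); when the column is a gap in the reference the position
collapses onto the count of preceding reference residues, which keeps the
measure total and deterministic.  The default near-match ceiling is 30 nt
— wide enough to cover the observed 7/23 bp cases with margin — and is a
reporting radius, not a homology statement.  Matrix building rejects two
genes of one family in one taxon rather than silently merging paralogs.

## Dollo reconstruction

Each character arises once (re-insertion at the same codon and phase is
vanishingly unlikely relative to loss) and may be lost repeatedly.  The
closed form — gain above MRCA(possessors), presence on the minimal
spanning subtree, one loss per maximal empty subtree hanging off it — is
the event-count optimum among single-origin scenarios; the test suite
verifies this against exhaustive enumeration of all single-gain state
assignments on random trees of up to 8 leaves.  Multifurcations are
allowed (a possessor-free polytomy child is one loss subtree).  Singleton
characters get a terminal-branch gain; they are reported like any other
character but are weak evidence by nature.  Unnamed internal nodes are
auto-labelled with the sorted tuple of descendant leaves so reports are
stable across runs and serialisations.

One invariant sometimes expected of such reconstructions — that adding a
possessor taxon cannot increase the loss count — is false in general (a
distant added possessor can pull the gain rootward past several empty
subtrees); what does hold, and is tested, is that the gain node never
moves *toward* the leaves.

## The lineage fixture

The packaged fixture encodes, at the level of 11 lineages, which
intron-position characters each lineage carries in the two paralogs
(7 characters for *slc26a1*, 6 for *slc26a2*), plus the two candidate
resolutions of the Euteleostei backbone.  Lineages rather than all
sampled species are used because the within-lineage structures are
uniform and event counts are invariant to expanding a leaf into a clade
of identical rows.  Character columns are presence/absence only; the
fixture deliberately carries no per-intron nucleotide coordinates, which
appear only graphically in the source material — all event-level
quantities (gain counts between named nodes, loss placements, ancestral
exon counts, per-topology totals) depend only on the matrix and tree.
Unsupported resolutions inside Euteleostei and inside Eurypterygii are
left as polytomies rather than asserted.

## TE signature detectors

**TSD.**  All exact L-mers (default 3–10 nt) occurring once near the 5′
splice junction and once near the 3′ one (within a 10-nt window; each
occurrence is assigned to the junction it is nearest to, so the two
copies genuinely bracket the element) are reported, longest first.
Repeats may straddle the junctions — in transposon-derived introns the
splice gt/ag can fall inside the duplication — with an exon-only mode
available.

**TIR.**  Prefix/suffix arms are compared against each other's reverse
complement, extended greedily from the 8-nt minimum while identity stays
above 1 − 0.2; a small end-slop (≤4 nt trimmed per end) absorbs element
boundaries that do not coincide with the splice sites.

**Tandem period.**  For each candidate unit k the sequence is
shift-matched at lag k and the best-supported window located by a
weighted maximum-sum scan (mismatch weight −4 encodes the 0.8 fraction
threshold).  The reported unit is the one whose window covers the most
matching positions, with exact ties to the smallest k — so a 74-nt lag
never shadows a true 37-nt unit.  Literal fraction maximisation is
degenerate on random DNA (tiny all-match windows at short lags reach
fraction 1.0 by chance), so a call additionally requires three copies'
worth of span and ≥10 matching positions; two-copy arrays are therefore
below the reporting floor, a deliberate sensitivity/false-positive
trade-off.  Sub-periods shorter than the minimum unit trigger a
low-complexity flag (homopolymers report the smallest admissible unit,
flagged).

**Interspersed copies.**  Exact 13-mer seeds are chained by diagonal
(±10 nt), extended greedily through matching bases, and scored ungapped
on the dominant diagonal; hits need ≥50 % query coverage and ≥80 %
identity, overlapping hits collapse to one locus, and the query's own
locus can be excluded.  An intron similar to ≥3 distinct loci (default)
is classified a putative transposable element; TSD/TIR/tandem evidence is
bundled in the report but does not gate the call, mirroring how
interspersal alone defines mobility.

## Synthetic data

The gene simulator's stated world: a root CDS of 300 codons evolving on a
user tree; intron gains as a Poisson process (default 0.4 per unit branch
length, ~6 expected gains on the default 8-leaf unit-branch tree) at
uniformly drawn, never-reused (codon, phase) sites, so zero homoplasy by
construction (a homoplasy-on switch exists for stress testing); losses
optional; uniform amino-acid substitutions (0.05/site/unit) — no rate
matrix, since only coordinate bookkeeping, not phylogenetic signal, is
exercised, and the true alignment is emitted so alignment inference stays
out of scope.  Codon-aligned indels are optional; the true alignment is
maintained through global column identifiers, deletions never remove
intron anchor codons or the first codon, and leaf contigs are written
with gt…ag introns of 60–120 nt.  Replaying the truth log reproduces every
leaf structure; this is asserted in tests.

The TE-intron generator plants, by default, the construct its detectors
are specified against: a 4-nt TSD straddling the junctions (the first
copy ends with the intron's gt, the second begins with its ag — which
constrains the duplication to the form ``ag…gt`` and makes 4 nt the
minimum possible length), 12-nt TIR arms beginning ``tgt``/ending
``aca``, and a central 37-nt unit repeated four times with two point
mutations.  Random portions are redrawn until no accidental direct repeat
longer than the planted TSD brackets the junctions (and, with the TSD
disabled, until none of ≥4 nt does): the instance must represent its own
truth annotation exactly, in the same spirit as the no-homoplasy rule.

A green end-to-end test on these simulations establishes that the
pipeline's bookkeeping (positions, phases, projection, clustering, event
inference) is exact under the stated world.  It does *not* establish
robustness to alignment error, frameshifted annotations, non-canonical
splice sites, or rate heterogeneity — real data exercise none of those
through the simulator.

## Numerical and degenerate-input choices

Ties in TSD ranking break by 5′-junction proximity, then position; ties
in tandem-unit selection break to the smallest unit; topology-comparison
ties break to input order.  Splice checks on introns shorter than 4 nt
flag rather than raise.  Empty projection sets yield a taxa × 0 matrix
and an empty event map rather than an error.  All randomness flows
through one seeded NumPy generator per run; identical seed and
configuration give byte-identical datasets.
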