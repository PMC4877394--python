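# Methods

This note documents the models, algorithms and numerical choices behind
plastcomp, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## Coordinates and data model

All coordinates are 0-based half-open. On circular genomes a feature may
wrap the origin; such intervals are stored with `end > length` so interval
arithmetic stays uniform (GenBank `join(x..L,1..y)` compound locations and
GFF3 exon pairs flagged `circular=true` are re-joined at the boundary).
Exons are ordered along the transcription direction, so a minus-strand
gene's first exon has the largest genomic coordinate. Trans-spliced genes
(rps12) are one gene whose exons may be distant; in gene-order analyses
their position defaults to the downstream exon block (configurable),
because that block behaves as the gene's locus in rearrangement terms.

Gene names are normalized to a canonical catalog: tRNAs use the
anticodon-in-parentheses convention (`trnK(uuu)`), rRNAs are `rrs`, `rrl`,
`rrf`. The packaged catalog distinguishes the 144-gene complement inferred
for the streptophyte chloroplast ancestor from the 90 genes universally
retained across the compared genomes; the difference (42 protein genes, 11
tRNAs and the tmRNA gene `ssrA`) is the set of genes lost at least once.
Features annotated only as ORFs are retained in the data model but excluded
from standard-gene analyses by category filter. Because rearrangement
analyses are sometimes restricted to an 89-gene shared set, the catalog
exposes both definitions (`shared_gene_set(exclude=...)`).

## Quadripartite architecture

The large IR is found as the longest pair of disjoint reverse-complementary
segments, located by exact k-mer seeding (k = 32) between the doubled
sequence and its reverse complement, merging seed runs along diagonals —
merged runs are exactly the maximal matches, so the detected IR is already
maximally extended at both junctions. Rotation invariance on circular
genomes comes from working on the doubled sequence and canonicalizing arm
intervals modulo the genome length. Ties in length are broken in favor of
the pair whose arms contain an rRNA gene (the IR is defined by the rDNA
operon it carries), then by smallest start coordinate. The two single-copy
gaps are named by length alone: the shorter is the SSC, even when gene
content is unusual. IR copies in finished organelle assemblies are
typically identical, so exact matching is the default; a mismatch-tolerant
mode extends arms greedily while the mismatch fraction stays below a
threshold, and the arm identity fraction is always reported.

Genes are assigned to IR/SSC/LSC by the region holding the majority of
their coding length; junction-straddling genes are flagged. The ancestral
partitioning score takes a reference genome with ancestral architecture,
labels each shared gene `ssc-side` or `lsc-side` relative to the rDNA
operon, and reports the minimum number of genes whose removal leaves the
target's circular order with each side in one contiguous arc. That minimum
is computed exactly in O(m²) by scanning every candidate arc with prefix
sums (the spec's exact/greedy split is unnecessary at organelle scale,
where m ≤ ~150); an exhaustive subset-removal oracle checks it on small
instances.

## Gene order, adjacencies and synteny

Signed adjacencies are canonicalized so that (a,b) and (−b,−a) are the same
pair, which makes adjacency sets invariant under rotation and full reverse
complement. The shared-pair matrix keeps pairs observed in at least
`min_taxa` (default 3) genomes; in a taxon where either member gene is
absent the pair is coded missing (?) rather than absent, so gene loss is
not misread as rearrangement.

Synteny blocks are maximal runs of genes consecutive in both genomes with
consistent relative orientation, computed on the common gene set with one
copy per gene. Genes unique to one genome are invisible to block
boundaries; they are handled afterwards by the missing-gene classifier,
which calls a gene a clean internal excision when its two flanking shared
genes are adjacent within one block of the other genome, and
breakpoint-associated otherwise. Circular orders are cut at a deterministic
anchor (the lexicographically smallest shared gene, reflected to +
orientation) and the block spanning the cut is re-merged, so block counts
are rotation-invariant and symmetric in the two genomes. Duplicated shared
genes outside the IR are resolved to the copy pair minimizing breakpoints,
ties by coordinate.

## Reversal distance

The exact minimum number of signed reversals uses the breakpoint graph:
elements are doubled (+x → 2x−1,2x; −x → 2x,2x−1) and capped with 0 and
2n+1; black edges join consecutive positions, gray edges consecutive
values. With c alternating cycles, h hurdles and fortress indicator f, the
distance is d = n + 1 − c + h + f. A gray edge spanning positions (p, q) is
oriented iff p + q is even; components are connected components of
cycle interleaving (crossing gray edges); a component is unoriented when
none of its gray edges is oriented; a hurdle is an unoriented component
that does not separate the other unoriented components on the circle of
positions (with pairwise nested-or-disjoint spans this reduces to
"contains none of them or contains all of them"); a hurdle is a
super-hurdle when deleting it turns another unoriented component into a
hurdle, and a fortress is an odd number of hurdles, all super. The
implementation is O(n²), ample for ≤150-gene organelle orders.

Circular orders are reduced to a canonical linear representative by
rotating (and reflecting if needed) so a fixed anchor gene sits first with
positive sign, then dropping it — sorting a circular order of n genes
equals sorting the resulting linear order of n−1. Correctness is asserted
against a breadth-first-search oracle over the full reversal graph for
n ≤ 7 (hundreds of random pairs, plus exhaustive sweeps of all positive
permutations, the hurdle-richest family) and against
rotation/reflection/relabeling invariance properties.

Branch lengths on a fixed topology are fitted by nonnegative least squares
of the pairwise distances against the tree's path-edge incidence matrix
(`scipy.optimize.nnls`). This is deliberately an approximation: exact
rearrangement branch lengths require median-genome (ancestral gene order)
reconstruction, which is NP-hard and out of scope; outputs are labeled
approximate, and on additive inputs the fit is exact with zero residual.

## Character evolution

Characters are binary with missing (?); matrices are built for gene
presence (ORFs excluded; optionally ? for unscreened genes of partial
genomes), intron sites (? where the host gene itself is absent, so host
loss is not double-counted as intron loss), signed gene pairs, and IR
presence. Under Dollo parsimony each character is gained once — at the
root when assumed ancestrally present (default for gene characters), else
at the MRCA of the taxa carrying it — and lost on a minimal set of
branches. The minimal set is computed exactly by recursion over the tree:
a subtree with no observed absence costs 0; one with no observed presence
costs one loss; a mixed subtree costs the sum over children. When a
character is absent everywhere but assumed present at the root, losses are
placed on the root's child branches (the root has no branch of its own).
Missing leaves impose no constraint, handled in the dynamic program rather
than by pruning taxa, so the topology is never distorted. When several
minimal placements exist the loss is pushed as deep as possible
(deterministic, latest-loss convention) and the number of alternative
minimal placements is reported. Multifurcations are supported; a loss on a
multifurcating child branch counts once. An exhaustive oracle enumerating
loss-branch subsets on ≤8-leaf trees verifies minimality on hundreds of
random instances.

The Fitch/Wagner variant is unit-cost Sankoff dynamic programming allowing
repeated gains (the two criteria coincide for binary characters); root
ties resolve to absence and child ties to the parent state, so
reconstructions are deterministic. Event summaries classify characters as
synapomorphic (exactly one event) or homoplasic (more), with loss-count
histograms and per-branch tables.

## Sequence statistics

G+C by codon position is computed over concatenated codons of the
protein-coding gene set, trimming incomplete terminal codons and warning on
internal stops. Small dispersed repeats are all maximal exact repeated
pairs ≥ 30 bp, direct and inverted, found with the same seed-and-merge
machinery as IR detection (the sequence is treated linearly, as
deposited); the large-IR arms are excluded by masking beforehand, since IR
bases would otherwise dominate the repeat fraction. Overlapping self-similar
(tandem) structures appear once per maximal pair; the masked footprint is
the merged union of all arms, and composition is summarized as G+C of
masked vs unmasked positions. An all-offsets quadratic oracle (numpy run
scanning) checks the finder exhaustively on ≤5 kb inputs.

Colinear divergence chains unique shared 31-mers (longest chain increasing
in both genomes), merges co-diagonal anchors into exact segments, and
globally aligns the inter-anchor gaps and flanks with edlib. Anchors that
reappear on a shifted diagonal are trimmed against the previous segment
rather than dropped, so indels inside locally repetitive sequence still
surface as alignable gaps. Substitutions are counted per position; each
maximal gap run counts as one indel event, so a pair with s substitutions
and e indels diverges at s + e sites. If the anchor chain covers less than
half of the shorter genome the pair is declared non-colinear and a partial
report is returned.

The tRNA decoding audit reads each tRNA's anticodon from its canonical
name and lists the sense codons in actual CDS usage that no encoded tRNA
can read. Two wobble models are always reported: strict organellar rules
(G34 reads C/U, U34 reads A/G, C34 reads G, A34 treated as inosine reading
U/C/A, with lysidine-modified trnI(cau) reading AUA and the elongator and
initiator methionine tRNAs reading AUG only), and the superwobble variant
in which an unmodified U34 reads all four codons of an unsplit family box.
The strict list is the default `undecodable` field; superwobble is needed
for the single-tRNA family boxes (e.g. the alanine box) even with the full
ancestral tRNA complement, which is why both lists are carried.

## The simulator

`simulate_ancestor` builds a circular quadripartite genome from the
144-gene ancestral catalog: the IR carries the rDNA operon in
transcription order (rrs, trnI(gau), trnA(ugc), rrl, rrf) plus trnR(acg) by
default; 12 genes go to the SSC and the rest to the LSC, separated by
random spacers of 80–250 bp at a genome-wide G+C of 0.32 — the gene counts,
genome scale (~140 kb) and composition of a typical streptophyte
chloroplast genome. Protein genes are stop-free random CDSs of 100–500
codons; rRNA lengths follow the real genes. A G+C-rich 40 bp repeat family
(6 copies, mixed orientations, intergenic) is planted so repeat summaries
have signal, mirroring the observation that dispersed repeats in these
genomes are G+C-richer than unique sequence. Intron sites are planted at
ten named real plastid positions, including the group I trnL(uaa)_35 site
and the trans-spliced rps12_114 site. Spacer bases at the four IR
junctions are set so the planted repeat is maximal — otherwise detection
would (correctly) extend past the planted coordinates.

`evolve_on_tree` applies branch-wise events in a fixed order (IR loss,
boundary shifts, gene losses, intron losses, intron gains, reversals, then
substitutions and indels), with Poisson counts scaled by branch length.
Reversal endpoints are intergenic and each reversal must span at least one
gene; while the IR exists reversals act within a single-copy region, and
any change to the IR is mirrored into both copies (concerted evolution).
Boundary shifts move whole genes between the IR and a single-copy region.
Indels are restricted to intergenic spacers (geometric lengths, mean 2),
so planted gene structures stay intact; substitutions fall anywhere. Under
`unique_losses` each gene, intron site and the IR can be lost at most once
across the whole history, giving the homoplasy-free scenarios used for
exact recovery checks. Every event is logged with absolute parameters, so
replaying the log reproduces each leaf byte-for-byte — an invariant under
test.

What the simulator does not emulate: selection and codon-usage bias,
realistic intergenic motifs, IR expansion by unequal recombination
(boundary shifts move whole genes only), intron secondary structure, and
sequence homology decay between duplicate genes. Passing tests therefore
demonstrate algorithmic correctness on structurally realistic genomes, not
robustness to the full noise spectrum of real annotations (mis-annotated
boundaries, pseudogenes, partial assemblies).

## Problem sizes and determinism

Default test and acceptance workloads are desk-scale by design: ~140 kb
genomes, 6–10 leaf trees, 200 oracle permutation pairs at n ≤ 7, 300–500
random Dollo instances at ≤8 leaves, 100 seeded replicates for reversal
recovery, ≤5 kb repeat-oracle inputs and one 100 kb divergence pair. All
randomness flows from a single integer seed (numpy Generator / stdlib
Random); the CLI records the seed and a configuration hash in its run
manifest, and identical configurations produce byte-identical reports.

## Known limitations

- Dollo loss placement is reported with a deterministic latest-loss
  tie-break; when missing states make the placement ambiguous (e.g. an
  intron loss whose host gene is later lost), the planted branch cannot be
  identified from leaf data even in principle — recovery checks therefore
  condition on characters whose hosts survive.
- The mismatch-tolerant IR mode extends greedily from exact seeds and is
  meant for lightly diverged arms, not for deeply eroded residual IRs.
- The repeat finder reports exact repeats only; diverged repeat families
  are out of scope, so masked fractions on real genomes are conservative
  relative to similarity-search tools.
- Branch lengths from pairwise distances are a least-squares approximation
  to rearrangement branch lengths, not a median-genome reconstruction.
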