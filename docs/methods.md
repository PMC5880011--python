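# Methods

This note documents the models, conventions, parameter choices and known
limitations of the package; it is the design record a maintainer should
read before changing defaults.

## Coordinate and phase conventions

All genomic coordinates are 0-based half-open on the forward strand;
GFF3's 1-based inclusive coordinates are converted at the I/O boundary and
nowhere else.  CDS offsets count coding nucleotides 5'→3' in coding
orientation, so intron phase is `offset % 3`: phase 0 lies between codons,
phase 1/2 after the first/second base of a codon.  (Displays that number
phases 1/2/3 correspond to 0/1/2 here.)  Minus-strand gene models store
exons in genomic order but assemble the CDS, intron sequences and splice
dinucleotides in coding orientation.  When a gene carries several mRNAs the
longest one is kept; the choice is arbitrary but fixed and documented.

## Dollo parsimony

A binary character may be gained exactly once and lost any number of times.
The minimal-loss reconstruction is closed-form: gain at the MRCA of present
leaves (a character seen in a single leaf is gained on that terminal
branch, so lineage-specific introns are counted as terminal-branch gains);
a node in the gain clade is ancestrally present iff its subtree retains a
present leaf; one loss per maximal absent subtree.  Multifurcations are
handled natively (one loss per absent child subtree).  The test suite
checks equivalence against exhaustive enumeration of all single-gain state
assignments on random trees of up to 8 leaves.  Missing data are not
modelled: the matrix is strictly binary, and incompletely sequenced taxa
should be dropped before reconstruction rather than coded as absent.

## Synthetic cohorts

The generator is the package's instrument for validation: it evolves
ancestral codon-chain genes down a rooted tree, where every codon carries a
unique inherited identity and each intron character is anchored to a
(codon identity, phase) pair.  Because anchors ride along with their
codons, orthologous intron positions remain identifiable after
frame-preserving single-codon indels, giving exact ground truth for the
conservation stage.  Per branch of length *t* it applies gene losses
(per-gene probability 1−e^(−rate·t)), intron losses (exact excision, no
footprint — matching the precise position-loss semantics the conservation
comparison assumes), genome-wide Poisson intron gains at fresh unoccupied
anchors (occupied draws are re-drawn and logged), codon-wise nucleotide
substitutions with stop-avoiding resampling (start and stop codons fixed),
and single-codon insertions/deletions that never delete an anchored codon.
Characters are Dollo-consistent by construction, which the truth object can
verify by brute force.

Default study conditions emulate an intron-rich compact algal genome
against intron-poorer relatives on a six-leaf tree: 300 genes of 100–300
codons, Poisson(2) ancestral introns per gene, intron lengths uniform
20–80 bp (mean ≈ 50), 97% canonical GT–AG signals, GC content 0.45, about
half the genes on the minus strand, high intron turnover (genome-wide gain
30 and per-intron loss 0.3 per unit branch length), gene loss 0.05,
substitutions 0.05 per coding site and codon indels 0.002 per codon per
unit length.  These were chosen once as realistic for the target system
and are not tuned per analysis; tests that need a specific regime (e.g.
substitutions-only for alignment-exact conservation) set it explicitly.

What the generator deliberately does not emulate: read-level sequencing
noise (counts are simulated directly), alternative-splicing event types
other than single-intron retention, frame-breaking indels, intron sequence
divergence after gain (each character keeps one sequence), paralogy, and
horizontal transfer.  Passing tests therefore demonstrate correctness of
the analysis logic under the stated statistical structure, not robustness
to annotation error or assembly artefacts in real data.

The count simulator draws per-sample junction totals from a negative
binomial (mean 50, dispersion 10) and retained reads binomially with
retention probability logit(ρ) = logit(0.2) + δ·1[condition B] + ε, with
planted effect δ = 2.0 on a 10% subset and Gaussian sample noise
ε (SD 0.2).  The noise term gives the permutation null realistic
within-group spread; no noise model is prescribed by the source analyses,
so the SD is configurable.

## Presence profiling and clustering

A hit passes at e-value ≤ 10⁻⁵ and query coverage strictly greater than
0.30 (the strict reading of "> 30%"); the cell records the best percent
identity among passing hits.  Presence here is hit-threshold presence: the
manual phylogeny-based orthology sieve used in curated studies (tree
inspection, HGT screening) is out of scope.  For clustering, absent cells
are imputed as identity 0 (configurable); rows and columns are pre-sorted
lexicographically so scipy's complete-linkage merge order is deterministic
under ties.

## Intron similarity screen

All-vs-all local alignment with megablast-like scoring (+2 match, −3
mismatch; a gap of length k costs 5 + 2k), one alignment per unordered
pair, reported at query coverage ≥ 0.5 and score ≥ 40.  The score threshold
stands in for an e-value cutoff of an external search engine that the
package does not call; it is exposed in the CLI and config.  The reported
coverage of a pair is the larger of the two per-direction coverages so the
deduplicated output carries one number per pair.

## Conservation mapping

The anchor residue for every phase is ⌊offset/3⌋ — a phase-0 intron is
anchored to the residue immediately following it.  Any fixed rule applied
identically to both species preserves the equal-column test; this one keeps
the arithmetic a single integer division.  The built-in global aligner
(BLOSUM62, gap open 10, extend 1, a gap of length k costing open + k·extend)
is used when no external alignment is supplied; externally produced
aligned FASTA takes precedence, since column numbering is alignment-
dependent.  Conservation is "same column and same phase against one or more
partner introns"; near-miss columns (intron sliding) are deliberately not
conserved.  A query intron is conserved if any partner matches, mirroring
multi-hit search practice.

## Retention consequences

The retained segment is read in the frame of the preceding exons.  A
premature termination codon is a stop codon whose three bases all lie
inside the retained intron (`ptc_scope=intron_only`, the default): this
locates the stop in the intron itself.  Frame-shifting introns can also
create stops in the shifted downstream exon sequence; whether those count
is ambiguous in the way such figures are usually reported, so
`ptc_scope=full_transcript` scans the entire retained transcript instead,
and the test suite quantifies how often the two scopes disagree.  The
standard nuclear code is assumed (stops TAA/TAG/TGA).

## Differential splicing

The upstream of this analysis in the original tool chain decomposes a
splice graph into alternatively spliced modules; with intron retention the
dominant event, this package uses an intron-centric simplification: each
intron's two-point retained/spliced distribution per group, compared by
√JSD with the published thresholds (0.25 statistic, 0.01 FDR).  Group
retention is read-count weighted (pooled within group).  Thresholds are
read as: "> 10×" strict, the 16×/8× expression levels inclusive
("specified to be", not "greater than"), detection = ≥ 1 spliced read.

With two replicates per condition, pure label permutation yields only
C(4,2) = 6 distinct splits — far too few for FDR control at 0.01 — so the
null combines label randomisation with binomial resampling of each
sample's retained count under the pooled retention proportion;
p = (1 + #{null ≥ observed}) / (1 + n_null) with n_null = 10 000 by
default, and q-values are Benjamini–Hochberg (the FDR procedure is not
otherwise specified).  JSD is computed between group-mean distributions
(not averaged over per-sample pairs); both choices are flagged as open in
the source description of the method.  Whether a sample lands in group A
is re-drawn per null replicate, so unequal per-sample depths propagate
into the null.

Fold-change DE calling normalises to counts-per-million; the pseudo-count
of 1 floors the denominator mean only, so a 100-vs-250 normalised pair
sits exactly at fold change 2.5 and is called (inclusive threshold), while
all-zero denominators stay finite.

## Numerical and determinism notes

√JSD uses base-2 logarithms (0·log 0 ≡ 0), making the statistic exactly 1
for disjoint distributions; vectorised entropy clamps negative rounding
residue at 0.  All simulation and testing randomness flows through
numpy Generator objects seeded explicitly; `run-all` for a fixed seed is
byte-deterministic (the manifest records path basenames, not absolute
paths, so runs in different directories hash identically).  Problem sizes
in the shipped analyses — 300 genes, six species, 2 000 simulated introns,
10 000 null replicates — were chosen so each analysis step completes in
seconds while keeping Monte-Carlo standard errors well below the decision
thresholds they support.

## Known limitations

Intron extraction requires annotated exon chains (GFF3); the CDS↔genome
spliced-matching route used when only CDS FASTA is available assumes exact
exon matches, cannot recover micro-exons shorter than its 12-bp anchor
seed, and is not a general-purpose aligner.  The intron character
matrix merges positions by connected components of pairwise conservation
calls, so characters absent from the focal comparisons merge only if the
corresponding species pair was compared.  No NMD-target prediction, no
U12-intron detection, no splice-site strength models, and no handling of
unrooted trees.
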