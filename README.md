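# rhodosplice

Comparative analysis of spliceosome conservation and intron evolution in
compact genomes, motivated by the red algae (Rhodophyta): lineages that went
through severe genome reduction yet differ enormously in how much of the
RNA-splicing apparatus and how many spliceosomal introns they kept.  The
package implements the full desk analysis as a reusable, tested pipeline,
and ships a synthetic-cohort generator that plants known evolutionary ground
truth so every stage can be validated without any external data.

It is aimed at researchers in molecular evolution and comparative genomics
who want to profile gene presence/absence across a phylogeny, date gene and
intron losses, test cross-species intron-position conservation, and analyse
intron retention in RNA-seq derived junction counts.

## What it computes

**Presence profiling.** A reference protein set is searched against each
species (12-column tabular hit format); a gene is present where a hit has
e-value ≤ 10⁻⁵ and query coverage > 30%, recording the best percent
identity.  Profiles are clustered with Euclidean distance and complete
linkage.

**Dollo parsimony.** Binary characters (genes or intron positions) evolve by
a single gain and irreversible losses.  For a presence pattern over the
leaves of a rooted tree the minimal-loss history is unique: the gain sits at
the MRCA of all present leaves, and one loss is charged to each maximal
subtree of the gain clade with no present leaf.  This yields ancestral
inventories (e.g. the spliceosomal gene count in the common ancestor) and
per-branch loss tallies.

**Intron catalogs and position conservation.** Introns are extracted from
GFF3 exon chains with CDS offset and phase (offset mod 3), and the GT–AG
splice-signal fraction is reported.  To compare positions across species,
each intron is anchored to protein residue ⌊offset/3⌋ and projected to that
residue's column in a global protein alignment (BLOSUM62, affine gaps
10/1); two introns are conserved homologues iff they hit the same column
with the same phase.  Introns conserved nowhere are lineage-specific; those
shared with an outgroup are ancestral.

**Retention consequences.** Retaining an intron in the mature transcript is
classified in the upstream reading frame as premature-termination-codon
truncation (a stop wholly inside the intron), frame-shift (length not
divisible by 3), or clean in-frame insertion.

**Differential intron splicing.** From per-intron spliced/retained read
counts in two condition groups, after coverage filters (mean junction
coverage > 10×, detection in ≥ 4 samples, 16×/8× exon/intron expression),
each intron's two-point retained/spliced distribution is compared between
groups with the square root of the Jensen–Shannon divergence (base-2 logs,
√JSD ∈ [0,1]); significance uses a label-randomised binomial-resampling
null with Benjamini–Hochberg FDR, calling introns with √JSD ≥ 0.25 and
q ≤ 0.01.  Differential gene expression is called at fold change ≥ 2.5 on
CPM-normalised counts.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
six-species cohort (300 genes, ~2 ancestral introns/gene, mean intron
length 50 bp, 97% GT–AG, high intron turnover, seed 1):

```bash
python analysis/01_simulate_cohort.py     # writes scratch/cohort
python analysis/02_genome_landscape.py
python analysis/03_sm_gene_dollo.py
python analysis/04_intron_conservation.py
python analysis/05_retention_consequences.py
python analysis/06_differential_splicing.py
```

Representative output (seed 1):

```
294 of 300 reference genes were present in the common ancestor (gain at the root)
estimated intron positions in the common ancestor: 509 (of 653 characters)
of 507 introns, retention leads to:
  premature stop codon (truncation): 64.5%
  frame-shift:                        65.9%
  clean in-frame insertion:           10.8%
507 introns, 397 pass filters, 49 called differential
planted effects: 51; recovered: 48 (94.1%); false calls: 1
```

i.e. the pipeline recovers the planted ancestral gene content, estimates the
ancestral intron inventory from position conservation plus Dollo
reconstruction, classifies what retaining each intron would do to the
protein, and recovers 94% of the planted differential-splicing effects with
one false call at FDR 0.01.

The same stages are available as a CLI
(`rhodosplice simulate|catalog|presence|dollo|conservation|retention|diffsplice|run-all`);
`rhodosplice run-all --simulate --seed 7` is byte-deterministic for a fixed
seed and writes a manifest with the SHA-256 of every output.

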