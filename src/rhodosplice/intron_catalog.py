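"""Per-species intron catalogs, genome-level statistics, and the intron
self-similarity screen.

Introns are derived from annotated exon chains: one record per inter-exon
gap, reported in coding orientation (minus-strand introns are
reverse-complemented), with the CDS offset (coding nucleotides preceding the
intron, 5'->3') and phase = offset mod 3.  An intron is canonical when its
coding-orientation sequence starts GT and ends AG.

Phase convention: 0/1/2 = number of coding nucleotides of the interrupted
codon preceding the intron.  (Displays that number phases 1/2/3 map 1->0,
2->1, 3->2.)
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .formats_io import (GeneModel, GenomeSet, MalformedRecordError,
                         reverse_complement)

__all__ = [
    "IntronRecord",
    "GenomeStats",
    "extract_introns",
    "compute_genome_stats",
    "intron_similarity_screen",
    "catalog_to_frame",
]


@dataclass
class IntronRecord:
    species_id: str
    gene_id: str
    intron_index: int  # 0-based, 5'->3' in coding orientation
    contig_id: str
    start: int  # genomic, 0-based half-open, forward strand
    end: int
    strand: str
    cds_offset: int  # coding nucleotides preceding the intron
    sequence: str  # coding orientation

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def phase(self) -> int:
        return self.cds_offset % 3

    @property
    def donor_dinucleotide(self) -> str:
        return self.sequence[:2]

    @property
    def acceptor_dinucleotide(self) -> str:
        return self.sequence[-2:]

    @property
    def is_canonical(self) -> bool:
        return self.donor_dinucleotide == "GT" and self.acceptor_dinucleotide == "AG"

    @property
    def key(self) -> str:
        return f"{self.species_id}|{self.gene_id}|{self.intron_index}"


@dataclass
class GenomeStats:
    species_id: str
    gene_count: int
    single_exon_fraction: float
    multi_exon_fraction: float
    introns_per_gene: float
    mean_intron_length: float
    median_intron_length: float
    canonical_fraction: float
    gc_fraction: float
    intergenic_fraction: float


def extract_introns(models: list[GeneModel], genome: GenomeSet) -> list[IntronRecord]:
    """One record per inter-exon gap of every gene model."""
    records: list[IntronRecord] = []
    for m in models:
        gaps = []
        for (s0, e0), (s1, e1) in zip(m.exons, m.exons[1:]):
            if s1 == e0:
                raise MalformedRecordError(
                    f"gene {m.gene_id}: zero-length gap between exons at {e0}")
            gaps.append((e0, s1))
        if m.strand == "-":
            gaps = gaps[::-1]  # coding order is descending genomic order
        cds_offset = 0
        coding_exons = m.exons_coding_order()
        for idx, (gstart, gend) in enumerate(gaps):
            cds_offset += coding_exons[idx][1] - coding_exons[idx][0]
            seq = genome.slice(m.contig_id, gstart, gend)
            if m.strand == "-":
                seq = reverse_complement(seq)
            records.append(IntronRecord(
                species_id=m.species_id, gene_id=m.gene_id, intron_index=idx,
                contig_id=m.contig_id, start=gstart, end=gend, strand=m.strand,
                cds_offset=cds_offset, sequence=seq))
    return records


def compute_genome_stats(catalog: list[IntronRecord], models: list[GeneModel],
                         genome: GenomeSet) -> GenomeStats:
    if not models:
        raise ValueError("empty model list")
    n_genes = len(models)
    n_multi = sum(1 for m in models if m.n_exons > 1)
    lengths = [r.length for r in catalog]
    lengths_s = pd.Series(lengths, dtype=float)
    gc = acgt = 0
    for seq in genome.sequences.values():
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    gene_span = sum(m.span[1] - m.span[0] for m in models)
    return GenomeStats(
        species_id=genome.species_id,
        gene_count=n_genes,
        single_exon_fraction=(n_genes - n_multi) / n_genes,
        multi_exon_fraction=n_multi / n_genes,
        introns_per_gene=len(catalog) / n_genes,
        mean_intron_length=float(lengths_s.mean()) if lengths else 0.0,
        median_intron_length=float(lengths_s.median()) if lengths else 0.0,
        canonical_fraction=(sum(r.is_canonical for r in catalog) / len(catalog)
                            if catalog else float("nan")),
        gc_fraction=gc / acgt if acgt else float("nan"),
        intergenic_fraction=1.0 - gene_span / genome.total_length,
    )


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def intron_similarity_screen(catalog: list[IntronRecord],
                             min_query_coverage: float = 0.5,
                             min_score: float = 40.0,
                             match: float = 2.0, mismatch: float = -3.0,
                             gap_open: float = 5.0, gap_extend: float = 2.0
                             ) -> pd.DataFrame:
    """All-vs-all local alignment screen for mutually similar introns.

    One alignment per unordered pair; a pair is reported when the aligned
    query span covers >= ``min_query_coverage`` of the shorter-coverage
    direction's query (the larger of the two per-direction coverages) and
    the local score is >= ``min_score``.  Self-pairs are excluded and output
    is deduplicated to unordered pairs.
    """
    if len(catalog) < 2:
        return pd.DataFrame(columns=["intron_a", "intron_b", "coverage", "score"])
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    rows = []
    for i, a in enumerate(catalog):
        for b in catalog[i + 1:]:
            aln = aligner.align(a.sequence, b.sequence)
            score = aln.score
            if score < min_score:
                continue
            best = aln[0]
            blocks_a, blocks_b = best.aligned
            span_a = int(blocks_a[-1][1] - blocks_a[0][0])
            span_b = int(blocks_b[-1][1] - blocks_b[0][0])
            coverage = max(span_a / len(a.sequence), span_b / len(b.sequence))
            if coverage >= min_query_coverage:
                rows.append({"intron_a": a.key, "intron_b": b.key,
                             "coverage": round(coverage, 4),
                             "score": float(score)})
    return pd.DataFrame(rows, columns=["intron_a", "intron_b", "coverage", "score"])


_SEED = 12


def _spliced_match(cds: str, contig: str, min_intron: int = 4
                   ) -> list[tuple[int, int]] | None:
    """Exact spliced alignment of a CDS onto one contig strand.

    Recursive exact matching with backtracking: extend the current exon
    maximally, then re-anchor the remaining CDS downstream via a short
    seed, allowing the junction to back off a few bases when the intron
    happens to start with the same bases as the next exon.  Candidate
    junctions with GT...AG signals are tried first.  Returns exon
    intervals, or None when no exact chain exists (exact-match semantics:
    the CDS must derive verbatim from this assembly).
    """
    seed0 = cds[:min(_SEED, len(cds))]
    start = contig.find(seed0)
    while start != -1:
        exons = _chain(cds, contig, 0, start, min_intron, 0)
        if exons is not None:
            return exons
        start = contig.find(seed0, start + 1)
    return None


def _chain(cds, contig, c, p, min_intron, depth):
    m = 0
    while (c + m < len(cds) and p + m < len(contig)
           and contig[p + m] == cds[c + m]):
        m += 1
    if c + m == len(cds):
        return [(p, p + m)]
    if m == 0 or depth > 60:
        return None
    candidates = []
    for j in range(m, max(m - 6, 0), -1):
        seed_len = min(_SEED, len(cds) - (c + j))
        if seed_len < 4:
            continue
        seed = cds[c + j:c + j + seed_len]
        q = contig.find(seed, p + j + min_intron)
        tries = 0
        while q != -1 and tries < 50:
            canonical = (contig[p + j:p + j + 2] == "GT"
                         and contig[q - 2:q] == "AG")
            candidates.append((0 if canonical else 1, q, -j))
            q = contig.find(seed, q + 1)
            tries += 1
    for _, q, neg_j in sorted(candidates):
        j = -neg_j
        rest = _chain(cds, contig, c + j, q, min_intron, depth + 1)
        if rest is not None:
            return [(p, p + j)] + rest
    return None


def infer_gene_model_from_cds(gene_id: str, cds: str, genome: GenomeSet
                              ) -> GeneModel | None:
    """Recover a gene model from a CDS alone by exact spliced matching.

    Tries both strands of every contig; exact-match semantics (no
    mismatches), so this suits CDS sets derived from the same assembly.
    Returns None when no exact spliced placement exists.
    """
    for contig_id, seq in genome.sequences.items():
        exons = _spliced_match(cds, seq)
        if exons is not None:
            return GeneModel(gene_id=gene_id, species_id=genome.species_id,
                             contig_id=contig_id, strand="+", exons=exons,
                             cds_sequence=cds)
        rc_exons = _spliced_match(cds, reverse_complement(seq))
        if rc_exons is not None:
            L = len(seq)
            exons = sorted((L - e, L - s) for s, e in rc_exons)
            return GeneModel(gene_id=gene_id, species_id=genome.species_id,
                             contig_id=contig_id, strand="-", exons=exons,
                             cds_sequence=cds)
    return None


def catalog_to_frame(catalog: list[IntronRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "species_id": [r.species_id for r in catalog],
        "gene_id": [r.gene_id for r in catalog],
        "intron_index": [r.intron_index for r in catalog],
        "contig_id": [r.contig_id for r in catalog],
        "start": [r.start for r in catalog],
        "end": [r.end for r in catalog],
        "strand": [r.strand for r in catalog],
        "length": [r.length for r in catalog],
        "cds_offset": [r.cds_offset for r in catalog],
        "phase": [r.phase for r in catalog],
        "donor": [r.donor_dinucleotide for r in catalog],
        "acceptor": [r.acceptor_dinucleotide for r in catalog],
        "is_canonical": [r.is_canonical for r in catalog],
        "sequence": [r.sequence for r in catalog],
    })


def stats_to_frame(stats: list[GenomeStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])
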