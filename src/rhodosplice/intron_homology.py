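"""Cross-species intron-position conservation in protein-alignment space.

Intron positions along a CDS are not directly comparable between species
because of indels and variable terminal extensions, so each intron is
anchored to a protein residue (the residue spanning or immediately following
the splice point: ``floor(cds_offset / 3)``) and projected to the column of
that residue in a pairwise protein alignment.  Two introns are conserved
homologues when they project to the same column and carry the same phase.
An intron conserved in no other species is lineage-specific; one conserved
in at least one outgroup species is ancestral; otherwise it is shared within
the ingroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import ReferenceError_, SpeciesTree
from .intron_catalog import IntronRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinAlignment",
    "IntronHomologyCall",
    "align_proteins_global",
    "intron_to_column",
    "call_conservation",
    "classify_lineage_specificity",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYBZXJUO")


@dataclass
class ProteinAlignment:
    """Two gapped protein sequences of equal length, keyed by sequence id."""

    ids: tuple[str, str]
    gapped: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.gapped[0]) != len(self.gapped[1]):
            raise ValueError("gapped sequences differ in length")
        self._col_of = []
        for g in self.gapped:
            cols = [i for i, c in enumerate(g) if c != "-"]
            self._col_of.append(cols)

    def ungapped(self, which: int) -> str:
        return self.gapped[which].replace("-", "")

    def column_of_residue(self, seq_id: str, residue_index: int) -> int:
        which = self.ids.index(seq_id)
        cols = self._col_of[which]
        if residue_index >= len(cols):
            raise ReferenceError_(
                f"{seq_id}: residue {residue_index} beyond protein length "
                f"{len(cols)} (annotation/translation mismatch)")
        return cols[residue_index]

    @property
    def identity(self) -> float:
        a, b = self.gapped
        pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        if not pairs:
            return 0.0
        return sum(x == y for x, y in pairs) / len(pairs)


def align_proteins_global(seq_a: str, seq_b: str, id_a: str = "a",
                          id_b: str = "b", matrix_name: str = "BLOSUM62",
                          gap_open: float = 10.0, gap_extend: float = 1.0
                          ) -> ProteinAlignment:
    """Optimal global alignment with affine gaps (gap of length k costs
    ``gap_open + k * gap_extend``); traceback is Biopython's deterministic
    first-alignment order."""
    for name, s in ((id_a, seq_a), (id_b, seq_b)):
        if not s:
            raise ValueError(f"{name}: empty sequence")
        bad = sorted(set(s) - _AA)
        if bad:
            raise ValueError(f"{name}: non-amino-acid characters {bad}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    best = aligner.align(seq_a, seq_b)[0]
    gapped_a, gapped_b = str(best[0]), str(best[1])
    return ProteinAlignment(ids=(id_a, id_b), gapped=(gapped_a, gapped_b))


def intron_to_column(intron: IntronRecord, alignment: ProteinAlignment,
                     seq_id: str | None = None) -> tuple[int, int]:
    """Project an intron to (alignment column of its anchor residue, phase).

    The anchor residue is ``floor(cds_offset / 3)`` for every phase, so a
    phase-0 intron anchors to the residue immediately following it.
    """
    sid = seq_id if seq_id is not None else intron.gene_id
    residue = intron.cds_offset // 3
    return alignment.column_of_residue(sid, residue), intron.phase


@dataclass
class IntronHomologyCall:
    intron_a: str  # IntronRecord.key
    intron_b: str
    species_a: str
    species_b: str
    column_a: int
    column_b: int
    phase_a: int
    phase_b: int

    @property
    def conserved(self) -> bool:
        return self.column_a == self.column_b and self.phase_a == self.phase_b


def call_conservation(catalog_a: list[IntronRecord], catalog_b: list[IntronRecord],
                      alignments: dict[tuple[str, str], ProteinAlignment],
                      ortholog_pairs: list[tuple[str, str]]
                      ) -> list[IntronHomologyCall]:
    """Compare intron columns/phases for every ortholog pair.

    ``alignments`` maps (gene_a, gene_b) to a pairwise protein alignment
    whose sequence ids are the gene ids.  Pairs without an alignment are
    skipped with a warning.  Every cross-species intron pair within an
    ortholog pair yields one call; an intron is conserved if any of its
    calls is conserved.
    """
    by_gene_a: dict[str, list[IntronRecord]] = {}
    for r in catalog_a:
        by_gene_a.setdefault(r.gene_id, []).append(r)
    by_gene_b: dict[str, list[IntronRecord]] = {}
    for r in catalog_b:
        by_gene_b.setdefault(r.gene_id, []).append(r)

    calls: list[IntronHomologyCall] = []
    for gene_a, gene_b in ortholog_pairs:
        aln = alignments.get((gene_a, gene_b))
        if aln is None:
            logger.warning("no alignment for ortholog pair (%s, %s); skipped",
                           gene_a, gene_b)
            continue
        for ra in by_gene_a.get(gene_a, []):
            col_a, ph_a = intron_to_column(ra, aln, seq_id=aln.ids[0])
            for rb in by_gene_b.get(gene_b, []):
                col_b, ph_b = intron_to_column(rb, aln, seq_id=aln.ids[1])
                calls.append(IntronHomologyCall(
                    intron_a=ra.key, intron_b=rb.key,
                    species_a=ra.species_id, species_b=rb.species_id,
                    column_a=col_a, column_b=col_b,
                    phase_a=ph_a, phase_b=ph_b))
    return calls


def conserved_partners(calls: list[IntronHomologyCall]) -> dict[str, set[str]]:
    """Map each intron key to the set of species it is conserved in."""
    out: dict[str, set[str]] = {}
    for c in calls:
        if c.conserved:
            out.setdefault(c.intron_a, set()).add(c.species_b)
            out.setdefault(c.intron_b, set()).add(c.species_a)
    return out


def classify_lineage_specificity(calls: list[IntronHomologyCall],
                                 tree: SpeciesTree, focal_species: str,
                                 outgroup_set: set[str],
                                 focal_catalog: list[IntronRecord]
                                 ) -> dict[str, str]:
    """Label every focal intron lineage_specific / shared_ingroup / ancestral.

    lineage_specific: conserved in no other species; ancestral: conserved in
    >= 1 outgroup species; shared_ingroup: conserved only within the ingroup.
    """
    if focal_species not in tree.leaves():
        raise ReferenceError_(f"focal species {focal_species!r} not in tree")
    seen_species = {c.species_a for c in calls} | {c.species_b for c in calls}
    if focal_species not in seen_species:
        raise ReferenceError_(
            f"focal species {focal_species!r} absent from conservation calls")
    partners = conserved_partners(calls)
    labels: dict[str, str] = {}
    for r in focal_catalog:
        conserved_in = partners.get(r.key, set()) - {focal_species}
        if not conserved_in:
            labels[r.key] = "lineage_specific"
        elif conserved_in & outgroup_set:
            labels[r.key] = "ancestral"
        else:
            labels[r.key] = "shared_ingroup"
    return labels


def build_intron_character_matrix(all_calls: list[IntronHomologyCall],
                                  catalogs: dict[str, list[IntronRecord]]):
    """Cluster introns into positional characters (connected components of
    the conserved-pair graph; unconnected introns are singleton characters)
    and return a binary characters x species presence matrix."""
    import pandas as pd

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            # deterministic representative: lexicographically smallest
            lo, hi = sorted((rx, ry))
            parent[hi] = lo

    species_of: dict[str, str] = {}
    for sp, catalog in catalogs.items():
        for r in catalog:
            find(r.key)
            species_of[r.key] = sp
    for c in all_calls:
        if c.conserved:
            union(c.intron_a, c.intron_b)
    members: dict[str, set[str]] = {}
    for key in species_of:
        members.setdefault(find(key), set()).add(species_of[key])
    cols = sorted(catalogs)
    data = {rep: [int(sp in spp) for sp in cols]
            for rep, spp in sorted(members.items())}
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)
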