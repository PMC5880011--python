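"""Readers and writers for on-disk formats, and the home of coordinate conventions.

Conventions used throughout the package:

* Genomic coordinates are 0-based, half-open, on the forward strand.
  GFF3 (1-based, inclusive) is converted at the I/O boundary and nowhere else.
* CDS offsets count coding nucleotides 5'->3' in coding orientation, 0-based,
  so the phase of a position is simply ``offset % 3``.
* Tabular homology hits use the classic 12-column tab-separated dialect
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore) with 1-based inclusive alignment coordinates; query
  lengths are supplied separately because the format omits them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomeSet",
    "GeneModel",
    "SpeciesTree",
    "HitTable",
    "MalformedRecordError",
    "ReferenceError_",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_newick",
    "write_newick",
    "read_hit_table",
    "write_hit_table",
    "reverse_complement",
]

HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MalformedRecordError(ValueError):
    """A feature/record violates the format contract (names the offender)."""


class ReferenceError_(KeyError):
    """An identifier refers to an entity that does not exist."""


# ---------------------------------------------------------------------------
# Genomes and gene models
# ---------------------------------------------------------------------------

@dataclass
class GenomeSet:
    """All contigs of one species, keyed by contig id (uppercase nucleotides)."""

    species_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq:
                raise MalformedRecordError(f"contig {cid!r} is empty")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def slice(self, contig_id: str, start: int, end: int) -> str:
        if contig_id not in self.sequences:
            raise ReferenceError_(f"unknown contig {contig_id!r}")
        return self.sequences[contig_id][start:end]


@dataclass
class GeneModel:
    """A strand-aware exon chain with its assembled CDS.

    ``exons`` are genomic intervals (0-based half-open) stored in ascending
    genomic order regardless of strand; ``cds_sequence`` is assembled 5'->3'
    in coding orientation (reverse-complemented for minus-strand genes).
    """

    gene_id: str
    species_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(f"gene {self.gene_id}: strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if e <= s:
                raise MalformedRecordError(f"gene {self.gene_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise MalformedRecordError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if len(self.cds_sequence) != self.exon_span_total:
            raise MalformedRecordError(
                f"gene {self.gene_id}: CDS length {len(self.cds_sequence)} != "
                f"summed exon length {self.exon_span_total}"
            )
        # Generator-produced models are clean ORFs; real annotations may not
        # be -- flag rather than reject.
        if len(self.cds_sequence) % 3 != 0:
            self.flags.append("cds_length_not_multiple_of_3")
        elif self.cds_sequence:
            if not self.cds_sequence.startswith("ATG"):
                self.flags.append("no_start_codon")
            if self.cds_sequence[-3:] not in ("TAA", "TAG", "TGA"):
                self.flags.append("no_stop_codon")

    @property
    def exon_span_total(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_coding_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @classmethod
    def from_exons(cls, gene_id: str, species_id: str, genome: GenomeSet,
                   contig_id: str, strand: str, exons: list[tuple[int, int]]) -> "GeneModel":
        exons = sorted(exons)
        parts = [genome.slice(contig_id, s, e) for s, e in exons]
        cds = "".join(parts)
        if strand == "-":
            cds = reverse_complement(cds)
        return cls(gene_id, species_id, contig_id, strand, exons, cds)

    @property
    def protein(self) -> str:
        """Translation of the CDS, trailing stop removed (standard code)."""
        aa = str(Seq(self.cds_sequence).translate())
        return aa[:-1] if aa.endswith("*") else aa


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike, genome: GenomeSet) -> list[GeneModel]:
    """Parse gene models from GFF3, one model per gene (longest mRNA kept).

    CDS features define the exon chain when present, plain exons otherwise.
    Coordinates are converted from GFF3 1-based inclusive to internal 0-based
    half-open at this boundary.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best: tuple[int, GeneModel] | None = None
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parents = mrnas if mrnas else [gene]
        for mrna in parents:
            segs = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if not segs:
                segs = list(db.children(mrna, featuretype="exon", order_by="start"))
            if not segs:
                continue
            if segs[0].seqid not in genome.sequences:
                raise ReferenceError_(
                    f"feature {mrna.id}: unknown contig {segs[0].seqid!r}")
            intervals = []
            prev_end = -1
            for seg in segs:
                start, end = seg.start - 1, seg.end  # 1-based incl -> 0-based half-open
                if start < prev_end:
                    raise MalformedRecordError(
                        f"mRNA {mrna.id}: overlapping CDS feature at "
                        f"{seg.seqid}:{seg.start}-{seg.end}")
                prev_end = end
                intervals.append((start, end))
            model = GeneModel.from_exons(
                gene_id=gene.id, species_id=genome.species_id,
                genome=genome, contig_id=segs[0].seqid,
                strand=gene.strand, exons=intervals)
            length = model.exon_span_total
            if best is None or length > best[0]:
                best = (length, model)
        if best is not None:
            models.append(best[1])
    return models


def write_gff3(path: str | os.PathLike, models: list[GeneModel],
               source: str = "rhodosplice") -> None:
    """Write gene/mRNA/exon/CDS features; inverse of :func:`read_gff3` on
    generator output (feature lines round-trip byte-identically)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda x: (x.contig_id, x.span[0], x.gene_id)):
            g0, g1 = m.span
            base = f"{m.contig_id}\t{source}"
            fh.write(f"{base}\tgene\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
            mid = f"{m.gene_id}.t1"
            fh.write(f"{base}\tmRNA\t{g0 + 1}\t{g1}\t.\t{m.strand}\t.\t"
                     f"ID={mid};Parent={m.gene_id}\n")
            # phase column: coding nucleotides carried over into each segment
            phases: dict[tuple[int, int], int] = {}
            carried = 0
            for s, e in m.exons_coding_order():
                phases[(s, e)] = (3 - carried % 3) % 3
                carried += e - s
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(f"{base}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={mid}.exon{i};Parent={mid}\n")
            for i, (s, e) in enumerate(m.exons, start=1):
                fh.write(f"{base}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t{phases[(s, e)]}\t"
                         f"ID={mid}.cds{i};Parent={mid}\n")


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    id: str
    parent: str | None
    children: list[str]
    length: float | None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class SpeciesTree:
    """A rooted tree with unique leaf labels and deterministic internal ids.

    Unlabelled internal nodes receive ids ``n<post-order index>``.  Branches
    are identified by their child node id.  Multifurcations are allowed; a
    trifurcation at the root is accepted but recorded in
    ``root_multifurcating``.
    """

    def __init__(self, nodes: dict[str, _Node], root: str):
        self.nodes = nodes
        self.root = root
        self.root_multifurcating = len(nodes[root].children) > 2
        self._postorder = self._compute_postorder()
        self._depth = {}
        for nid in self.preorder():
            p = self.nodes[nid].parent
            self._depth[nid] = 0 if p is None else self._depth[p] + 1

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      preserve_underscores=True)
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise MalformedRecordError(f"duplicate leaf labels: {exc}") from exc
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise MalformedRecordError(f"duplicate leaf labels: {dup}")
        nodes: dict[str, _Node] = {}
        order = list(dtree.postorder_node_iter())
        ids: dict[int, str] = {}
        for i, nd in enumerate(order):
            if nd.is_leaf():
                nid = nd.taxon.label
            elif nd.label:
                nid = nd.label
            else:
                nid = f"n{i}"
            if nid in ids.values() or nid in nodes:
                raise MalformedRecordError(f"duplicate node id {nid!r}")
            ids[id(nd)] = nid
            nodes[nid] = _Node(id=nid, parent=None, children=[], length=nd.edge.length)
        for nd in order:
            for ch in nd.child_nodes():
                nodes[ids[id(ch)]].parent = ids[id(nd)]
                nodes[ids[id(nd)]].children.append(ids[id(ch)])
        root = ids[id(dtree.seed_node)]
        return cls(nodes, root)

    def to_newick(self) -> str:
        def render(nid: str) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                s = node.id
            else:
                s = "(" + ",".join(render(c) for c in node.children) + ")" + node.id
            if node.length is not None:
                s += f":{node.length:g}"
            return s
        return render(self.root) + ";"

    # -- traversal ----------------------------------------------------------

    def _compute_postorder(self) -> list[str]:
        out: list[str] = []

        def walk(nid: str) -> None:
            for c in self.nodes[nid].children:
                walk(c)
            out.append(nid)

        walk(self.root)
        return out

    def postorder(self) -> list[str]:
        return list(self._postorder)

    def preorder(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def leaves(self) -> list[str]:
        return [n for n in self._postorder if self.nodes[n].is_leaf]

    def children(self, nid: str) -> list[str]:
        return list(self.nodes[nid].children)

    def parent(self, nid: str) -> str | None:
        return self.nodes[nid].parent

    def branch_length(self, nid: str) -> float | None:
        return self.nodes[nid].length

    def branches(self) -> list[str]:
        """All branches, identified by child node id (root excluded)."""
        return [n for n in self._postorder if n != self.root]

    def ancestors(self, nid: str, include_self: bool = False) -> list[str]:
        out = [nid] if include_self else []
        cur = self.nodes[nid].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def is_ancestor_or_self(self, anc: str, nid: str) -> bool:
        return anc in self.ancestors(nid, include_self=True)

    def mrca(self, leaf_ids: set[str] | list[str]) -> str:
        leaf_ids = list(leaf_ids)
        if not leaf_ids:
            raise ValueError("mrca of an empty set")
        for l in leaf_ids:
            if l not in self.nodes:
                raise ReferenceError_(f"unknown node {l!r}")
        common = set(self.ancestors(leaf_ids[0], include_self=True))
        for l in leaf_ids[1:]:
            common &= set(self.ancestors(l, include_self=True))
        # deepest common ancestor
        return max(common, key=lambda n: self._depth[n])

    def subtree_leaves(self, nid: str) -> list[str]:
        if nid not in self.nodes:
            raise ReferenceError_(f"unknown node {nid!r}")
        if self.nodes[nid].is_leaf:
            return [nid]
        out: list[str] = []
        stack = [nid]
        while stack:
            cur = stack.pop()
            if self.nodes[cur].is_leaf:
                out.append(cur)
            else:
                stack.extend(self.nodes[cur].children)
        return sorted(out)

    def clade_sets(self) -> set[frozenset[str]]:
        """Leaf-set of every internal node; topology fingerprint for tests."""
        return {frozenset(self.subtree_leaves(n)) for n in self._postorder
                if not self.nodes[n].is_leaf}


def read_newick(path: str | os.PathLike) -> SpeciesTree:
    with open(path) as fh:
        return SpeciesTree.from_newick(fh.read())


def write_newick(path: str | os.PathLike, tree: SpeciesTree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tabular homology hits
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """12-column tabular hits plus per-row query coverage."""

    rows: pd.DataFrame
    query_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.rows) and (self.rows["e_value"] < 0).any():
            raise MalformedRecordError("negative e-value")


def read_hit_table(path: str | os.PathLike, query_lengths: dict[str, int]) -> HitTable:
    """Read a 12-column tab-separated hit file and compute query coverage.

    Coverage of a row is ``(q_end - q_start + 1) / query_length`` (1-based
    inclusive alignment coordinates).
    """
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, names=HIT_COLUMNS,
                         comment="#", dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=HIT_COLUMNS)
    numeric = ["pct_identity", "aln_length", "mismatches", "gap_opens",
               "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and len(df):
            line = int(vals.index[vals.isna()][0]) + 1
            raise MalformedRecordError(
                f"{path}: non-numeric {col} at data line {line}")
        df[col] = vals
    for col in ["aln_length", "mismatches", "gap_opens",
                "q_start", "q_end", "s_start", "s_end"]:
        df[col] = df[col].astype(int)
    if len(df):
        missing = sorted(set(df["query_id"]) - set(query_lengths))
        if missing:
            raise ReferenceError_(f"queries missing from length map: {missing}")
        qlen = df["query_id"].map(query_lengths)
        df["query_coverage"] = (df["q_end"] - df["q_start"] + 1) / qlen
    else:
        df["query_coverage"] = pd.Series(dtype=float)
    return HitTable(rows=df.reset_index(drop=True), query_lengths=dict(query_lengths))


def write_hit_table(path: str | os.PathLike, table: HitTable) -> None:
    table.rows[HIT_COLUMNS].to_csv(str(path), sep="\t", header=False, index=False)
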