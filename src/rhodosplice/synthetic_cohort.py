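"""Synthetic multi-species cohorts with known intron gain/loss ground truth.

The generator evolves a set of ancestral protein-coding genes down a rooted
species tree.  Every gene is a chain of codon units, each carrying a unique
identity that is inherited along branches; intron characters are anchored to
a (codon identity, phase) pair, so orthologous intron positions remain
identifiable across species even after codon insertions and deletions shift
raw CDS offsets.  Along each branch the simulator applies, in order: gene
losses, intron losses (exact excision, no footprint), intron gains (a fresh
character at an unoccupied anchor), codon-wise nucleotide substitutions with
stop-avoiding resampling, and single-codon insertions/deletions.  Characters
are therefore Dollo-consistent by construction: gained exactly once, present
in a leaf iff the gain node is an ancestor and no loss occurred on the path.

A separate count simulator produces per-intron, per-sample spliced/retained
read counts with negative-binomial coverage and a condition-dependent
logit-scale retention shift for a planted fraction of introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (GeneModel, GenomeSet, SpeciesTree, reverse_complement,
                         write_fasta, write_gff3, write_newick, write_hit_table,
                         HitTable, HIT_COLUMNS)
from .splice_divergence import SplicingCountTable

__all__ = [
    "CohortParams",
    "CountSimParams",
    "IntronCharacter",
    "GeneCharacter",
    "CohortTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_counts",
    "simulate_count_table",
    "make_hit_tables",
    "write_cohort",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass
class CohortParams:
    """Study conditions for cohort simulation.

    Defaults emulate an intron-rich compact algal genome: about two introns
    per gene ancestrally, short introns (mean ~50 bp), 97% canonical GT-AG
    splice signals, and a high intron turnover along the tree.  Rates are
    events per unit branch length; ``intron_gain_rate`` is genome-wide,
    ``intron_loss_rate`` and ``gene_loss_rate`` are per intron / per gene,
    ``substitution_rate`` is per coding nucleotide site.
    """

    tree_newick: str = ("((gsu:0.30,cme:0.30)cyanidio:0.20,"
                        "(((ccr:0.15,gch:0.15)florideo:0.15,ppu:0.30)meso1:0.10,"
                        "pye:0.40)meso2:0.10)root;")
    n_genes: int = 300
    cds_length_range: tuple[int, int] = (300, 900)  # nt, forced to codon multiples
    ancestral_intron_rate: float = 2.0  # mean introns per ancestral gene (Poisson)
    intron_gain_rate: float = 30.0
    intron_loss_rate: float = 0.3
    gene_loss_rate: float = 0.05
    intron_length_range: tuple[int, int] = (20, 80)
    canonical_signal_fraction: float = 0.97
    substitution_rate: float = 0.05
    indel_rate: float = 0.002  # codon insertions/deletions per codon per unit length
    gc_content: float = 0.45
    minus_strand_fraction: float = 0.5
    intergenic_length_range: tuple[int, int] = (100, 300)
    duplicate_families: int = 0  # planted families of identical intron sequences
    duplicate_family_size: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("ancestral_intron_rate", "intron_gain_rate", "intron_loss_rate",
                     "gene_loss_rate", "substitution_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.canonical_signal_fraction <= 1.0:
            raise ValueError("canonical_signal_fraction must be in [0,1]")
        if self.intron_length_range[0] < 4:
            raise ValueError("minimum intron length is 4 (room for GT...AG)")
        if self.n_genes < 1 or self.cds_length_range[0] < 9:
            raise ValueError("need at least one gene of at least 3 codons")


@dataclass
class CountSimParams:
    """Conditions for the splicing-count simulator.

    Emulates a two-condition culture experiment (two samples per condition
    by default) with negative-binomial junction coverage and a logit-scale
    retention shift of ``effect_size`` planted in ``effect_introns`` of the
    introns under the second condition.
    """

    n_samples_per_condition: int = 2
    baseline_retention: float = 0.2
    effect_introns: float = 0.1
    effect_size: float = 2.0
    coverage_mean: float = 50.0
    coverage_dispersion: float = 10.0
    noise_sd: float = 0.2  # Gaussian noise on logit(retention), per intron x sample
    conditions: tuple[str, str] = ("cold", "heat")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.baseline_retention < 1.0:
            raise ValueError("baseline_retention must be in (0,1)")
        if not 0.0 <= self.effect_introns <= 1.0:
            raise ValueError("effect_introns must be in [0,1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValueError("coverage parameters must be > 0")
        if self.n_samples_per_condition < 1:
            raise ValueError("need >= 1 sample per condition")


@dataclass
class IntronCharacter:
    """One intron position as an evolutionary character."""

    char_id: str
    gene_char: str
    anchor_codon: int  # codon identity the intron precedes (at offset `phase`)
    phase: int
    sequence: str
    gain_node: str
    loss_branches: set[str] = field(default_factory=set)
    # species -> CDS offset at that leaf (offsets drift under indels)
    presence: dict[str, int] = field(default_factory=dict)

    @property
    def is_canonical(self) -> bool:
        return self.sequence[:2] == "GT" and self.sequence[-2:] == "AG"


@dataclass
class GeneCharacter:
    char_id: str
    gain_node: str
    loss_branches: set[str] = field(default_factory=set)
    presence: set[str] = field(default_factory=set)


@dataclass
class _Codon:
    uid: int
    nt: str


@dataclass
class _GeneState:
    gene_char: str
    codons: list[_Codon]
    # char_id -> (codon uid, phase); the intron sits `phase` nt into that codon
    introns: dict[str, tuple[int, int]]

    def clone(self) -> "_GeneState":
        return _GeneState(self.gene_char,
                          [_Codon(c.uid, c.nt) for c in self.codons],
                          dict(self.introns))

    def offset_of(self, codon_uid: int, phase: int) -> int:
        for idx, c in enumerate(self.codons):
            if c.uid == codon_uid:
                return 3 * idx + phase
        raise KeyError(codon_uid)

    @property
    def cds(self) -> str:
        return "".join(c.nt for c in self.codons)


@dataclass
class CohortTruth:
    """All planted events and per-species realisations."""

    tree: SpeciesTree
    intron_characters: dict[str, IntronCharacter]
    gene_characters: dict[str, GeneCharacter]
    # species -> gene_char -> list of codon uids, one per protein residue
    residue_maps: dict[str, dict[str, list[int]]]
    gains_per_branch: dict[str, int]

    def intron_presence_matrix(self) -> pd.DataFrame:
        """Binary characters x leaves matrix (characters seen in >= 1 leaf)."""
        leaves = self.tree.leaves()
        rows = {}
        for cid, ch in sorted(self.intron_characters.items()):
            if ch.presence:
                rows[cid] = [int(sp in ch.presence) for sp in leaves]
        return pd.DataFrame.from_dict(rows, orient="index", columns=leaves)

    def gene_presence_matrix(self) -> pd.DataFrame:
        leaves = self.tree.leaves()
        rows = {cid: [int(sp in ch.presence) for sp in leaves]
                for cid, ch in sorted(self.gene_characters.items()) if ch.presence}
        return pd.DataFrame.from_dict(rows, orient="index", columns=leaves)

    def intron_tuples(self, species: str) -> set[tuple[str, int, int, bool]]:
        """Truth (gene_id, cds_offset, phase, is_canonical) for one species."""
        out = set()
        for ch in self.intron_characters.values():
            if species in ch.presence:
                out.add((ch.gene_char, ch.presence[species], ch.phase,
                         ch.is_canonical))
        return out

    def shared_characters(self, sp_a: str, sp_b: str) -> set[str]:
        return {cid for cid, ch in self.intron_characters.items()
                if sp_a in ch.presence and sp_b in ch.presence}

    def ancestral_state(self, char: IntronCharacter, node: str) -> int:
        """Truth presence of a character at a node: 1 iff the node descends
        from the gain node and no loss branch lies on the path between them."""
        if not self.tree.is_ancestor_or_self(char.gain_node, node):
            return 0
        path = [n for n in [node, *self.tree.ancestors(node)]
                if self.tree.is_ancestor_or_self(char.gain_node, n)]
        return 0 if any(b in char.loss_branches for b in path) else 1

    def verify_dollo_consistency(self) -> bool:
        """Brute-force check: leaf presence == reachability from the gain."""
        for ch in self.intron_characters.values():
            for leaf in self.tree.leaves():
                expected = 0
                if self.tree.is_ancestor_or_self(ch.gain_node, leaf):
                    path = [n for n in [leaf, *self.tree.ancestors(leaf)]
                            if self.tree.is_ancestor_or_self(ch.gain_node, n)]
                    if not any(b in ch.loss_branches for b in path):
                        expected = 1
                if expected != int(leaf in ch.presence):
                    return False
        return True


@dataclass
class Cohort:
    params: CohortParams
    tree: SpeciesTree
    genomes: dict[str, GenomeSet]
    models: dict[str, list[GeneModel]]
    truth: CohortTruth
    reference_proteins: dict[str, str]  # ancestral (root) proteins by gene char
    root_residue_uids: dict[str, list[int]] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    while True:
        codon = "".join(rng.choice(list(_BASES), size=3, p=p))
        if codon not in _STOPS:
            return codon


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _random_intron_seq(rng: np.random.Generator, params: CohortParams) -> str:
    lo, hi = params.intron_length_range
    length = int(rng.integers(lo, hi + 1))
    middle = _random_dna(rng, length - 4, params.gc_content)
    if rng.random() < params.canonical_signal_fraction:
        return "GT" + middle + "AG"
    while True:
        donor = _random_dna(rng, 2, 0.5)
        acceptor = _random_dna(rng, 2, 0.5)
        if not (donor == "GT" and acceptor == "AG"):
            return donor + middle + acceptor


def simulate_cohort(params: CohortParams) -> Cohort:
    """Evolve genomes, gene models and intron characters down the tree."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    tree = SpeciesTree.from_newick(params.tree_newick)
    log: list[str] = []

    codon_uid = [0]

    def next_uid() -> int:
        codon_uid[0] += 1
        return codon_uid[0]

    intron_chars: dict[str, IntronCharacter] = {}
    gene_chars: dict[str, GeneCharacter] = {}
    intron_counter = [0]

    def new_intron_char(gene_char: str, codon: int, phase: int,
                        gain_node: str, sequence: str) -> str:
        cid = f"i{intron_counter[0]:05d}"
        intron_counter[0] += 1
        intron_chars[cid] = IntronCharacter(
            char_id=cid, gene_char=gene_char, anchor_codon=codon, phase=phase,
            sequence=sequence, gain_node=gain_node)
        return cid

    # --- ancestral genome at the root -------------------------------------
    root_state: dict[str, _GeneState] = {}
    lo, hi = params.cds_length_range
    for g in range(params.n_genes):
        gid = f"g{g:04d}"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        codons = [_Codon(next_uid(), "ATG")]
        codons += [_Codon(next_uid(), _random_codon(rng, params.gc_content))
                   for _ in range(n_codons - 2)]
        codons.append(_Codon(next_uid(), str(rng.choice(list(_STOPS)))))
        state = _GeneState(gid, codons, {})
        n_introns = int(rng.poisson(params.ancestral_intron_rate))
        for _ in range(n_introns):
            for _attempt in range(50):
                idx = int(rng.integers(1, len(codons) - 1))
                phase = int(rng.integers(0, 3))
                key = (codons[idx].uid, phase)
                if key not in state.introns.values():
                    seq = _random_intron_seq(rng, params)
                    cid = new_intron_char(gid, key[0], phase, tree.root, seq)
                    state.introns[cid] = key
                    break
            else:
                log.append(f"gene {gid}: could not place ancestral intron")
        root_state[gid] = state
        gene_chars[gid] = GeneCharacter(char_id=gid, gain_node=tree.root)

    # planted duplicate intron-sequence families (for the similarity screen)
    if params.duplicate_families and params.duplicate_family_size >= 2:
        ancestral = sorted(cid for cid, ch in intron_chars.items()
                           if ch.gain_node == tree.root)
        need = params.duplicate_families * params.duplicate_family_size
        if need <= len(ancestral):
            chosen = rng.choice(len(ancestral), size=need, replace=False)
            for f in range(params.duplicate_families):
                fam_seq = _random_intron_seq(rng, params)
                for k in range(params.duplicate_family_size):
                    cid = ancestral[int(chosen[f * params.duplicate_family_size + k])]
                    intron_chars[cid].sequence = fam_seq
        else:
            log.append("not enough ancestral introns for requested duplicate families")

    # --- evolve down the tree ----------------------------------------------
    node_states: dict[str, dict[str, _GeneState]] = {tree.root: root_state}
    gains_per_branch: dict[str, int] = {b: 0 for b in tree.branches()}

    for node in tree.preorder():
        if node == tree.root:
            continue
        parent_state = node_states[tree.parent(node)]
        t = tree.branch_length(node) or 0.0
        state = {gid: gs.clone() for gid, gs in parent_state.items()}

        # gene losses
        p_gene_loss = 1.0 - np.exp(-params.gene_loss_rate * t)
        for gid in sorted(state):
            if rng.random() < p_gene_loss:
                gene_chars[gid].loss_branches.add(node)
                for cid in state[gid].introns:
                    intron_chars[cid].loss_branches.add(node)
                del state[gid]

        # intron losses: exact excision
        p_intron_loss = 1.0 - np.exp(-params.intron_loss_rate * t)
        for gid in sorted(state):
            for cid in sorted(state[gid].introns):
                if rng.random() < p_intron_loss:
                    intron_chars[cid].loss_branches.add(node)
                    del state[gid].introns[cid]

        # intron gains (genome-wide Poisson)
        n_gain = int(rng.poisson(params.intron_gain_rate * t)) if state else 0
        for _ in range(n_gain):
            gid = sorted(state)[int(rng.integers(0, len(state)))]
            gs = state[gid]
            placed = False
            for _attempt in range(50):
                idx = int(rng.integers(1, len(gs.codons) - 1))
                phase = int(rng.integers(0, 3))
                key = (gs.codons[idx].uid, phase)
                if key not in gs.introns.values():
                    seq = _random_intron_seq(rng, params)
                    cid = new_intron_char(gid, key[0], phase, node, seq)
                    gs.introns[cid] = key
                    gains_per_branch[node] += 1
                    placed = True
                    break
            if not placed:
                log.append(f"branch {node}: intron gain redraw limit in {gid}")

        # codon-wise substitutions (stop-avoiding; start/stop codons fixed)
        for gid in sorted(state):
            gs = state[gid]
            n_sites = 3 * len(gs.codons)
            n_sub = int(rng.poisson(params.substitution_rate * t * n_sites))
            for _ in range(n_sub):
                idx = int(rng.integers(1, len(gs.codons) - 1))
                old = gs.codons[idx].nt
                for _attempt in range(20):
                    pos = int(rng.integers(0, 3))
                    base = _BASES[int(rng.integers(0, 4))]
                    if base == old[pos]:
                        continue
                    cand = old[:pos] + base + old[pos + 1:]
                    if cand not in _STOPS:
                        gs.codons[idx].nt = cand
                        break

        # single-codon indels (reading-frame preserving)
        for gid in sorted(state):
            gs = state[gid]
            n_indel = int(rng.poisson(params.indel_rate * t * len(gs.codons)))
            for _ in range(n_indel):
                if rng.random() < 0.5:
                    pos = int(rng.integers(1, len(gs.codons)))
                    gs.codons.insert(pos, _Codon(next_uid(),
                                                 _random_codon(rng, params.gc_content)))
                else:
                    occupied = {uid for uid, _ in gs.introns.values()}
                    candidates = [i for i in range(1, len(gs.codons) - 1)
                                  if gs.codons[i].uid not in occupied]
                    if not candidates:
                        log.append(f"branch {node}: no deletable codon in {gid}")
                        continue
                    pos = candidates[int(rng.integers(0, len(candidates)))]
                    del gs.codons[pos]

        node_states[node] = state

    # --- record leaf presence ----------------------------------------------
    for leaf in tree.leaves():
        for gid, gs in node_states[leaf].items():
            gene_chars[gid].presence.add(leaf)
            for cid, (uid, phase) in gs.introns.items():
                intron_chars[cid].presence[leaf] = gs.offset_of(uid, phase)

    # --- realise genomes, gene models, residue maps ------------------------
    strands = {f"g{g:04d}": ("-" if rng.random() < params.minus_strand_fraction
                             else "+") for g in range(params.n_genes)}
    genomes: dict[str, GenomeSet] = {}
    models: dict[str, list[GeneModel]] = {}
    residue_maps: dict[str, dict[str, list[int]]] = {}
    ig_lo, ig_hi = params.intergenic_length_range
    for leaf in tree.leaves():
        contig_parts: list[str] = []
        pos = 0
        contig_id = "chr1"
        sp_models: list[GeneModel] = []
        res_map: dict[str, list[int]] = {}
        for gid in sorted(node_states[leaf]):
            gs = node_states[leaf][gid]
            gap = _random_dna(rng, int(rng.integers(ig_lo, ig_hi + 1)),
                              params.gc_content)
            contig_parts.append(gap)
            pos += len(gap)
            cds = gs.cds
            # splice intron sequences into the transcript (coding orientation)
            inserts = sorted(((gs.offset_of(uid, ph), intron_chars[cid].sequence)
                              for cid, (uid, ph) in gs.introns.items()))
            pre_mrna_parts = []
            exon_bounds_tx: list[tuple[int, int]] = []  # in pre-mRNA coords
            cursor_cds = 0
            cursor_tx = 0
            for off, iseq in inserts:
                exon_len = off - cursor_cds
                pre_mrna_parts.append(cds[cursor_cds:off])
                exon_bounds_tx.append((cursor_tx, cursor_tx + exon_len))
                cursor_tx += exon_len
                pre_mrna_parts.append(iseq)
                cursor_tx += len(iseq)
                cursor_cds = off
            pre_mrna_parts.append(cds[cursor_cds:])
            exon_bounds_tx.append((cursor_tx, cursor_tx + len(cds) - cursor_cds))
            pre_mrna = "".join(pre_mrna_parts)
            strand = strands[gid]
            if strand == "+":
                segment = pre_mrna
                exons = [(pos + a, pos + b) for a, b in exon_bounds_tx]
            else:
                segment = reverse_complement(pre_mrna)
                L = len(pre_mrna)
                exons = sorted((pos + L - b, pos + L - a) for a, b in exon_bounds_tx)
            contig_parts.append(segment)
            pos += len(segment)
            sp_models.append(GeneModel(
                gene_id=gid, species_id=leaf, contig_id=contig_id,
                strand=strand, exons=exons, cds_sequence=cds))
            res_map[gid] = [c.uid for c in gs.codons[:-1]]  # stop codon excluded
        tail = _random_dna(rng, int(rng.integers(ig_lo, ig_hi + 1)), params.gc_content)
        contig_parts.append(tail)
        genomes[leaf] = GenomeSet(species_id=leaf,
                                  sequences={contig_id: "".join(contig_parts)})
        models[leaf] = sp_models
        residue_maps[leaf] = res_map

    reference_proteins = {gid: _translate(gs.cds)
                          for gid, gs in root_state.items()}
    root_residue_uids = {gid: [c.uid for c in gs.codons[:-1]]
                         for gid, gs in root_state.items()}
    truth = CohortTruth(tree=tree, intron_characters=intron_chars,
                        gene_characters=gene_chars, residue_maps=residue_maps,
                        gains_per_branch=gains_per_branch)
    return Cohort(params=params, tree=tree, genomes=genomes, models=models,
                  truth=truth, reference_proteins=reference_proteins,
                  root_residue_uids=root_residue_uids, log=log)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# Hit tables from truth
# ---------------------------------------------------------------------------

def make_hit_tables(cohort: Cohort) -> tuple[dict[str, HitTable], dict[str, int]]:
    """Emulated homology-search output: ancestral proteins as queries against
    each species' proteome.  Present genes yield one full-length hit whose
    identity is the residue identity over inherited codon positions; absent
    genes yield none.  Self-hits therefore always have query coverage 1.0."""
    query_lengths = {gid: len(p) for gid, p in cohort.reference_proteins.items()}
    tables: dict[str, HitTable] = {}
    for sp in cohort.tree.leaves():
        rows = []
        sp_models = {m.gene_id: m for m in cohort.models[sp]}
        for gid in sorted(cohort.reference_proteins):
            if gid not in sp_models:
                continue
            ref = cohort.reference_proteins[gid]
            prot = sp_models[gid].protein
            uid_map = cohort.truth.residue_maps[sp][gid]
            ref_by_uid = {u: ref[i]
                          for i, u in enumerate(cohort.root_residue_uids[gid])}
            matches = sum(1 for i, u in enumerate(uid_map)
                          if u in ref_by_uid and ref_by_uid[u] == prot[i])
            ident = 100.0 * matches / max(len(ref), 1)
            rows.append({
                "query_id": gid, "subject_id": f"{sp}|{gid}",
                "pct_identity": round(ident, 2), "aln_length": len(ref),
                "mismatches": len(ref) - matches, "gap_opens": 0,
                "q_start": 1, "q_end": len(ref),
                "s_start": 1, "s_end": len(prot),
                "e_value": 1e-50, "bit_score": round(2.0 * matches, 1),
            })
        df = pd.DataFrame(rows, columns=HIT_COLUMNS)
        if len(df):
            df["query_coverage"] = (df["q_end"] - df["q_start"] + 1) / df["query_id"].map(query_lengths)
        else:
            df["query_coverage"] = pd.Series(dtype=float)
        tables[sp] = HitTable(rows=df, query_lengths=dict(query_lengths))
    return tables, query_lengths


# ---------------------------------------------------------------------------
# Splicing-count simulation
# ---------------------------------------------------------------------------

def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def simulate_count_table(intron_ids: list[str], params: CountSimParams
                         ) -> tuple[SplicingCountTable, list[str]]:
    """Core count simulator over an explicit intron list.

    Returns the count table and the planted differential intron ids.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = len(intron_ids)
    if params.n_samples_per_condition < 1 or n == 0:
        raise ValueError("need >= 1 intron and >= 1 sample per condition")
    cond_a, cond_b = params.conditions
    conditions: dict[str, str] = {}
    samples: list[str] = []
    for cond in (cond_a, cond_b):
        for i in range(params.n_samples_per_condition):
            name = f"{cond}-{i + 1}"
            samples.append(name)
            conditions[name] = cond
    n_samples = len(samples)

    n_effect = int(round(params.effect_introns * n))
    planted_idx = rng.choice(n, size=n_effect, replace=False) if n_effect else np.array([], dtype=int)
    delta = np.zeros(n)
    delta[planted_idx] = params.effect_size

    nb_n = params.coverage_dispersion
    nb_p = nb_n / (nb_n + params.coverage_mean)
    total = rng.negative_binomial(nb_n, nb_p, size=(n, n_samples))
    is_b = np.array([conditions[s] == cond_b for s in samples])
    logit = (_logit(params.baseline_retention)
             + np.outer(delta, is_b.astype(float))
             + rng.normal(0.0, params.noise_sd, size=(n, n_samples)))
    rho = 1.0 / (1.0 + np.exp(-logit))
    retained = rng.binomial(total, rho)
    spliced = total - retained

    def frame(arr) -> pd.DataFrame:
        return pd.DataFrame(arr, index=intron_ids, columns=samples)

    table = SplicingCountTable(
        spliced=frame(spliced), retained=frame(retained),
        exon_coverage=frame(total), intron_coverage=frame(retained),
        conditions=conditions)
    planted = sorted(intron_ids[i] for i in planted_idx)
    return table, planted


def simulate_counts(truth: CohortTruth, focal_species: str,
                    params: CountSimParams) -> tuple[SplicingCountTable, list[str]]:
    """Simulate counts for every intron present in the focal species."""
    intron_ids = sorted(cid for cid, ch in truth.intron_characters.items()
                        if focal_species in ch.presence)
    if not intron_ids:
        raise ValueError(f"no introns present in {focal_species!r}")
    return simulate_count_table(intron_ids, params)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort directory: per-species FASTA/GFF3/proteins, the tree,
    emulated hit tables, and truth tables."""
    import os
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "hits"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
    write_newick(os.path.join(outdir, "tree.nwk"), cohort.tree)
    for sp in cohort.tree.leaves():
        write_fasta(os.path.join(outdir, f"{sp}.genome.fasta"),
                    cohort.genomes[sp].sequences)
        write_gff3(os.path.join(outdir, f"{sp}.gff3"), cohort.models[sp])
        write_fasta(os.path.join(outdir, f"{sp}.proteins.fasta"),
                    {m.gene_id: m.protein for m in cohort.models[sp]})
    write_fasta(os.path.join(outdir, "reference.proteins.fasta"),
                cohort.reference_proteins)
    tables, qlens = make_hit_tables(cohort)
    pd.Series(qlens, name="length").to_csv(
        os.path.join(outdir, "query_lengths.tsv"), sep="\t",
        index_label="query_id")
    for sp, table in tables.items():
        write_hit_table(os.path.join(outdir, "hits", f"{sp}.hits.tsv"), table)
    rows = []
    leaves = cohort.tree.leaves()
    for cid, ch in sorted(cohort.truth.intron_characters.items()):
        rows.append({
            "char_id": cid, "gene": ch.gene_char, "phase": ch.phase,
            "gain_node": ch.gain_node,
            "loss_branches": ",".join(sorted(ch.loss_branches)),
            "canonical": ch.is_canonical,
            **{f"offset_{sp}": ch.presence.get(sp, -1) for sp in leaves},
        })
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth",
                                           "intron_characters.tsv"),
                              sep="\t", index=False)
    grows = [{"char_id": cid, "gain_node": ch.gain_node,
              "loss_branches": ",".join(sorted(ch.loss_branches)),
              **{f"present_{sp}": int(sp in ch.presence) for sp in leaves}}
             for cid, ch in sorted(cohort.truth.gene_characters.items())]
    pd.DataFrame(grows).to_csv(os.path.join(outdir, "truth",
                                            "gene_characters.tsv"),
                               sep="\t", index=False)
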