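"""Protein alignment, intron-to-column projection, conservation calling."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from rhodosplice.intron_catalog import IntronRecord, extract_introns
from rhodosplice.intron_homology import (IntronHomologyCall, ProteinAlignment,
                                         align_proteins_global,
                                         call_conservation,
                                         classify_lineage_specificity,
                                         conserved_partners, intron_to_column)
from rhodosplice.synthetic_cohort import CohortParams, simulate_cohort

GAP_OPEN, GAP_EXT = 10.0, 1.0


def exhaustive_affine_score(a, b, matrix, gap_open=GAP_OPEN, gap_ext=GAP_EXT):
    """Best global alignment score by exhaustive enumeration of all
    alignments (a gap run of length k costs gap_open + k * gap_ext)."""
    best = [-np.inf]

    def walk(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_ext if last == "a" else gap_open + gap_ext
            walk(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_ext if last == "b" else gap_open + gap_ext
            walk(i, j + 1, score - cost, "b")

    walk(0, 0, 0.0, "m")
    return best[0]


def _aligned_score(aln: ProteinAlignment, matrix) -> float:
    score = 0.0
    run = None
    for x, y in zip(*aln.gapped):
        if x == "-" or y == "-":
            gap = "a" if x == "-" else "b"
            score -= GAP_EXT if run == gap else GAP_OPEN + GAP_EXT
            run = gap
        else:
            score += matrix[x, y]
            run = None
    return score


class TestGlobalAlignment:
    def test_identical_sequences_align_gapless(self):
        aln = align_proteins_global("MKVLITG", "MKVLITG")
        assert aln.gapped == ("MKVLITG", "MKVLITG")
        assert aln.identity == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins_global("", "MKV")

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            align_proteins_global("MK1V", "MKV")

    def test_score_matches_exhaustive_oracle_on_short_pairs(self):
        """Alignment score equals brute-force enumeration over all global
        alignments for short sequences (4-letter amino-acid alphabet)."""
        matrix = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(11)
        alphabet = "ACDE"
        for _ in range(30):
            la, lb = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(alphabet), la))
            b = "".join(rng.choice(list(alphabet), lb))
            aln = align_proteins_global(a, b)
            assert _aligned_score(aln, matrix) == pytest.approx(
                exhaustive_affine_score(a, b, matrix)), (a, b)


def _intron(gene, offset, species="sp", seq="GTAAAG" * 5 + "AG"):
    return IntronRecord(species_id=species, gene_id=gene, intron_index=0,
                        contig_id="c", start=0, end=len(seq), strand="+",
                        cds_offset=offset, sequence=seq)


class TestIntronToColumn:
    def test_ungapped_projection(self):
        aln = ProteinAlignment(ids=("g1", "g2"), gapped=("M" * 150, "M" * 150))
        col, phase = intron_to_column(_intron("g1", 300), aln)
        assert (col, phase) == (100, 0)

    def test_gaps_before_anchor_shift_column(self):
        gapped_a = "M" * 50 + "-" * 5 + "M" * 100
        gapped_b = "M" * 155
        aln = ProteinAlignment(ids=("g1", "g2"), gapped=(gapped_a, gapped_b))
        col, phase = intron_to_column(_intron("g1", 300), aln)
        assert col == 105  # residue 100 sits after 5 gap columns

    def test_gap_columns_outside_anchor_span_are_irrelevant(self):
        aln1 = ProteinAlignment(ids=("g1", "g2"), gapped=("MMMM", "MMMM"))
        aln2 = ProteinAlignment(ids=("g1", "g2"),
                                gapped=("MMMM--", "MMMMKK"))
        i = _intron("g1", 6)
        assert intron_to_column(i, aln1)[0] == intron_to_column(i, aln2)[0]

    def test_phase_arithmetic(self):
        aln = ProteinAlignment(ids=("g1", "g2"), gapped=("M" * 150, "M" * 150))
        assert intron_to_column(_intron("g1", 301), aln) == (100, 1)
        assert intron_to_column(_intron("g1", 302), aln) == (100, 2)

    def test_anchor_beyond_protein_rejected(self):
        aln = ProteinAlignment(ids=("g1", "g2"), gapped=("MMM", "MMM"))
        with pytest.raises(KeyError, match="mismatch"):
            intron_to_column(_intron("g1", 9), aln)


def _truth_alignment(cohort, sp_a, sp_b, gene):
    """Gold-standard pairwise alignment from the generator's inherited
    residue identities (shared identities align, private ones gap)."""
    ua = cohort.truth.residue_maps[sp_a][gene]
    ub = cohort.truth.residue_maps[sp_b][gene]
    prot = {sp: {m.gene_id: m.protein for m in cohort.models[sp]}
            for sp in (sp_a, sp_b)}
    common = set(ua) & set(ub)
    ga, gb = [], []
    i = j = 0
    while i < len(ua) or j < len(ub):
        if i < len(ua) and ua[i] not in common:
            ga.append(prot[sp_a][gene][i]); gb.append("-"); i += 1
        elif j < len(ub) and ub[j] not in common:
            ga.append("-"); gb.append(prot[sp_b][gene][j]); j += 1
        else:
            ga.append(prot[sp_a][gene][i]); gb.append(prot[sp_b][gene][j])
            i += 1; j += 1
    return ProteinAlignment(ids=(f"{sp_a}|{gene}", f"{sp_b}|{gene}"),
                            gapped=("".join(ga), "".join(gb)))


def _conservation_vs_truth(cohort, sp_a, sp_b, use_truth_alignment):
    from dataclasses import replace
    cats = {sp: extract_introns(cohort.models[sp], cohort.genomes[sp])
            for sp in (sp_a, sp_b)}
    prot = {sp: {m.gene_id: m.protein for m in cohort.models[sp]}
            for sp in (sp_a, sp_b)}
    shared_genes = sorted(set(prot[sp_a]) & set(prot[sp_b]))
    alignments, pairs = {}, []
    for g in shared_genes:
        key = (f"{sp_a}|{g}", f"{sp_b}|{g}")
        if use_truth_alignment:
            alignments[key] = _truth_alignment(cohort, sp_a, sp_b, g)
        else:
            aln = align_proteins_global(prot[sp_a][g], prot[sp_b][g])
            alignments[key] = ProteinAlignment(ids=key, gapped=aln.gapped)
        pairs.append(key)
    ca = [replace(r, gene_id=f"{sp_a}|{r.gene_id}") for r in cats[sp_a]]
    cb = [replace(r, gene_id=f"{sp_b}|{r.gene_id}") for r in cats[sp_b]]
    calls = call_conservation(ca, cb, alignments, pairs)
    conserved = {(c.intron_a, c.intron_b) for c in calls if c.conserved}
    # truth: characters present in both species, keyed the same way
    offset_to_key = {
        sp_a: {(r.gene_id.split("|")[1], r.cds_offset): r.key for r in ca},
        sp_b: {(r.gene_id.split("|")[1], r.cds_offset): r.key for r in cb},
    }
    truth_pairs = set()
    for cid in cohort.truth.shared_characters(sp_a, sp_b):
        ch = cohort.truth.intron_characters[cid]
        truth_pairs.add((offset_to_key[sp_a][(ch.gene_char, ch.presence[sp_a])],
                         offset_to_key[sp_b][(ch.gene_char, ch.presence[sp_b])]))
    return conserved, truth_pairs, calls


class TestConservationCalling:
    def test_same_column_different_phase_not_conserved(self):
        aln = ProteinAlignment(ids=("a|g", "b|g"),
                               gapped=("M" * 50, "M" * 50))
        calls = call_conservation(
            [_intron("a|g", 30, species="a")],
            [_intron("b|g", 31, species="b")],
            {("a|g", "b|g"): aln}, [("a|g", "b|g")])
        [call] = calls
        assert call.column_a == call.column_b
        assert not call.conserved

    def test_calls_are_symmetric(self, cohort_no_indel):
        conserved_ab, _, _ = _conservation_vs_truth(
            cohort_no_indel, "gsu", "ccr", use_truth_alignment=False)
        conserved_ba, _, _ = _conservation_vs_truth(
            cohort_no_indel, "ccr", "gsu", use_truth_alignment=False)
        assert {(b, a) for a, b in conserved_ba} == conserved_ab

    def test_exact_recovery_without_indels(self, cohort_no_indel):
        """Substitutions only: built-in alignments recover the true shared
        intron set with zero false positives or negatives."""
        conserved, truth_pairs, _ = _conservation_vs_truth(
            cohort_no_indel, "gsu", "ccr", use_truth_alignment=False)
        assert conserved == truth_pairs

    def test_exact_recovery_with_indels_on_truth_alignment(self):
        """With codon indels the projection machinery still recovers the
        shared set exactly when given the gold-standard alignment."""
        cohort = simulate_cohort(CohortParams(seed=19, n_genes=40,
                                              indel_rate=0.02))
        conserved, truth_pairs, _ = _conservation_vs_truth(
            cohort, "gsu", "ccr", use_truth_alignment=True)
        assert conserved == truth_pairs

    def test_missing_alignment_skips_pair(self, caplog):
        calls = call_conservation([_intron("a|g", 30)], [_intron("b|g", 30)],
                                  {}, [("a|g", "b|g")])
        assert calls == []


class TestLineageSpecificity:
    def _call(self, a, b, sp_a, sp_b, conserved=True):
        return IntronHomologyCall(
            intron_a=a, intron_b=b, species_a=sp_a, species_b=sp_b,
            column_a=10, column_b=10 if conserved else 11,
            phase_a=0, phase_b=0)

    def test_definition_cases(self):
        from rhodosplice.formats_io import SpeciesTree
        tree = SpeciesTree.from_newick("((foc:1,sis:1)in:1,out:1)root;")
        focal_cat = [_intron("g1", 3, species="foc"),
                     _intron("g2", 3, species="foc"),
                     _intron("g3", 3, species="foc")]
        focal_cat[1].gene_id = "g2"
        calls = [
            self._call(focal_cat[0].key, "x", "foc", "sis", conserved=False),
            self._call(focal_cat[1].key, "y", "foc", "sis", conserved=True),
            self._call(focal_cat[2].key, "z", "foc", "out", conserved=True),
        ]
        labels = classify_lineage_specificity(calls, tree, "foc", {"out"},
                                              focal_cat)
        assert labels[focal_cat[0].key] == "lineage_specific"
        assert labels[focal_cat[1].key] == "shared_ingroup"
        assert labels[focal_cat[2].key] == "ancestral"

    def test_focal_absent_from_calls_rejected(self):
        from rhodosplice.formats_io import SpeciesTree
        tree = SpeciesTree.from_newick("((foc:1,sis:1)in:1,out:1)root;")
        calls = [self._call("a", "b", "sis", "out")]
        with pytest.raises(KeyError):
            classify_lineage_specificity(calls, tree, "foc", set(), [])

    def test_lineage_specific_fraction_equals_terminal_gains_without_loss(self):
        """No losses, no divergence: an intron is lineage-specific iff its
        character was gained on the focal terminal branch."""
        cohort = simulate_cohort(CohortParams(
            seed=23, n_genes=40, intron_loss_rate=0.0, gene_loss_rate=0.0,
            substitution_rate=0.0, indel_rate=0.0))
        focal = "gsu"
        others = [sp for sp in cohort.tree.leaves() if sp != focal]
        all_calls = []
        focal_cat = None
        for other in others:
            conserved, _, calls = _conservation_vs_truth(
                cohort, focal, other, use_truth_alignment=False)
            all_calls.extend(calls)
        from dataclasses import replace
        focal_cat = [replace(r, gene_id=f"{focal}|{r.gene_id}")
                     for r in extract_introns(cohort.models[focal],
                                              cohort.genomes[focal])]
        labels = classify_lineage_specificity(all_calls, cohort.tree, focal,
                                              set(), focal_cat)
        n_specific = sum(1 for v in labels.values() if v == "lineage_specific")
        terminal_gains = sum(
            1 for ch in cohort.truth.intron_characters.values()
            if ch.gain_node == focal and focal in ch.presence)
        assert n_specific == terminal_gains
        assert len(labels) == len(focal_cat)
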