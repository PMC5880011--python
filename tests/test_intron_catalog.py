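"""Intron extraction, genome statistics, and the similarity screen."""

import pytest

from rhodosplice.formats_io import GeneModel, GenomeSet, reverse_complement
from rhodosplice.intron_catalog import (compute_genome_stats, extract_introns,
                                        intron_similarity_screen)
from rhodosplice.synthetic_cohort import CohortParams, simulate_cohort


def _model(genome, exons, strand="+", gene_id="g1"):
    return GeneModel.from_exons(gene_id, "sp", genome, "c1", strand, exons)


@pytest.fixture
def two_exon_genome():
    # exon1 = ATGGCA, intron = GTxxxAG (9 bp), exon2 = GCATAA
    seq = "ATGGCA" + "GTCCCCCAG" + "GCATAA"
    return GenomeSet("sp", {"c1": seq})


class TestExtraction:
    def test_single_exon_gene_yields_nothing(self, two_exon_genome):
        m = _model(two_exon_genome, [(0, 6)])
        assert extract_introns([m], two_exon_genome) == []

    def test_forward_intron_fields(self, two_exon_genome):
        m = _model(two_exon_genome, [(0, 6), (15, 21)])
        [r] = extract_introns([m], two_exon_genome)
        assert (r.start, r.end, r.length) == (6, 15, 9)
        assert r.cds_offset == 6 and r.phase == 0
        assert r.sequence == "GTCCCCCAG"
        assert r.is_canonical

    def test_minus_strand_reports_coding_orientation(self):
        # same gene as above but laid out on the minus strand
        fwd = "ATGGCA" + "GTCCCCCAG" + "GCATAA"
        genome = GenomeSet("sp", {"c1": reverse_complement(fwd)})
        L = len(fwd)
        exons = sorted((L - b, L - a) for a, b in [(0, 6), (15, 21)])
        m = _model(genome, exons, strand="-")
        assert m.cds_sequence == "ATGGCAGCATAA"
        [r] = extract_introns([m], genome)
        assert r.sequence == "GTCCCCCAG"
        assert r.cds_offset == 6
        assert r.is_canonical

    def test_catalog_matches_generator_truth(self, small_cohort):
        for sp in small_cohort.tree.leaves():
            catalog = extract_introns(small_cohort.models[sp],
                                      small_cohort.genomes[sp])
            got = {(r.gene_id, r.cds_offset, r.phase, r.is_canonical)
                   for r in catalog}
            assert got == small_cohort.truth.intron_tuples(sp)

    def test_catalog_size_equals_exon_gaps(self, small_cohort):
        sp = small_cohort.tree.leaves()[0]
        catalog = extract_introns(small_cohort.models[sp],
                                  small_cohort.genomes[sp])
        assert len(catalog) == sum(m.n_exons - 1 for m in small_cohort.models[sp])

    def test_phase_recomputable_from_exon_lengths(self, small_cohort):
        sp = small_cohort.tree.leaves()[1]
        models = {m.gene_id: m for m in small_cohort.models[sp]}
        for r in extract_introns(small_cohort.models[sp], small_cohort.genomes[sp]):
            coding = models[r.gene_id].exons_coding_order()
            upstream = sum(e - s for s, e in coding[:r.intron_index + 1])
            assert r.cds_offset == upstream
            assert r.phase == upstream % 3

    def test_strand_symmetry(self, two_exon_genome):
        """Reverse-complementing the contig and flipping strands yields the
        same catalog up to coordinate reflection."""
        m = _model(two_exon_genome, [(0, 6), (15, 21)])
        [fwd] = extract_introns([m], two_exon_genome)
        seq = two_exon_genome.sequences["c1"]
        L = len(seq)
        flipped = GenomeSet("sp", {"c1": reverse_complement(seq)})
        exons = sorted((L - e, L - s) for s, e in m.exons)
        m2 = _model(flipped, exons, strand="-")
        [rev] = extract_introns([m2], flipped)
        assert (rev.sequence, rev.cds_offset, rev.phase) == \
            (fwd.sequence, fwd.cds_offset, fwd.phase)
        assert (rev.start, rev.end) == (L - fwd.end, L - fwd.start)


class TestSplicedMatching:
    def test_cds_only_inference_recovers_annotated_models(self, small_cohort):
        """Exact spliced matching of each CDS against the genome recovers
        the annotated exon chain and strand on both strands for every gene
        whose exons are all at least one anchor seed long (micro-exons
        below the seed length are a documented limitation)."""
        from rhodosplice.intron_catalog import _SEED, infer_gene_model_from_cds
        sp = small_cohort.tree.leaves()[0]
        genome = small_cohort.genomes[sp]
        checked = {"+": 0, "-": 0}
        for m in small_cohort.models[sp][:30]:
            if min(e - s for s, e in m.exons) < _SEED:
                continue
            inferred = infer_gene_model_from_cds(m.gene_id, m.cds_sequence,
                                                 genome)
            assert inferred is not None, m.gene_id
            assert inferred.exons == m.exons
            assert inferred.strand == m.strand
            checked[m.strand] += 1
        assert checked["+"] > 5 and checked["-"] > 5

    def test_foreign_cds_returns_none(self, small_cohort):
        from rhodosplice.intron_catalog import infer_gene_model_from_cds
        sp = small_cohort.tree.leaves()[0]
        cds = "ATG" + "CAT" * 40 + "TAA"
        assert infer_gene_model_from_cds("x", cds,
                                         small_cohort.genomes[sp]) is None


class TestGenomeStats:
    def test_all_single_exon(self):
        genome = GenomeSet("sp", {"c1": "ATGGCAGCATAA" * 4})
        models = [_model(genome, [(0, 12)], gene_id="g1"),
                  _model(genome, [(12, 24)], gene_id="g2")]
        stats = compute_genome_stats([], models, genome)
        assert stats.single_exon_fraction == 1.0
        assert stats.multi_exon_fraction == 0.0
        assert stats.introns_per_gene == 0.0

    def test_gc_fraction_half_for_atgc_repeat(self):
        genome = GenomeSet("sp", {"c1": "ATGC" * 30})
        models = [_model(genome, [(0, 12)])]
        stats = compute_genome_stats([], models, genome)
        assert stats.gc_fraction == pytest.approx(0.5)

    def test_empty_model_list_rejected(self):
        with pytest.raises(ValueError):
            compute_genome_stats([], [], GenomeSet("sp", {"c1": "ACGT"}))

    def test_cohort_stats_match_generator_conditions(self, small_cohort):
        sp = "gsu"
        catalog = extract_introns(small_cohort.models[sp], small_cohort.genomes[sp])
        stats = compute_genome_stats(catalog, small_cohort.models[sp],
                                     small_cohort.genomes[sp])
        params = small_cohort.params
        lo, hi = params.intron_length_range
        assert lo <= stats.mean_intron_length <= hi
        # canonical fraction near the configured probability (binomial spread)
        assert abs(stats.canonical_fraction - params.canonical_signal_fraction) < 0.08
        assert 0.0 < stats.intergenic_fraction < 1.0


class TestSimilarityScreen:
    def _record(self, seq, key):
        from rhodosplice.intron_catalog import IntronRecord
        return IntronRecord(species_id="sp", gene_id=key, intron_index=0,
                            contig_id="c1", start=0, end=len(seq), strand="+",
                            cds_offset=3, sequence=seq)

    def test_identical_pair_full_coverage(self):
        seq = "GT" + "ACGTTGCA" * 7 + "AG"
        pairs = intron_similarity_screen([self._record(seq, "a"),
                                          self._record(seq, "b")])
        assert len(pairs) == 1
        assert pairs.iloc[0]["coverage"] == pytest.approx(1.0)

    def test_subthreshold_coverage_excluded(self):
        import numpy as np
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        block = "".join(rng.choice(bases, 40))
        a = block + "".join(rng.choice(bases, 60))
        b = block + "".join(rng.choice(bases, 60))
        # shared block covers only 0.4 of each 100-bp intron
        pairs = intron_similarity_screen([self._record(a, "a"),
                                          self._record(b, "b")],
                                         min_query_coverage=0.5)
        assert len(pairs) == 0
        relaxed = intron_similarity_screen([self._record(a, "a"),
                                            self._record(b, "b")],
                                           min_query_coverage=0.35)
        assert len(relaxed) == 1

    def test_planted_family_members_pair_with_each_other(self):
        cohort = simulate_cohort(CohortParams(
            seed=17, n_genes=30, duplicate_families=1, duplicate_family_size=4,
            intron_gain_rate=0.0, intron_loss_rate=0.0, gene_loss_rate=0.0,
            ancestral_intron_rate=1.0))
        sp = cohort.tree.leaves()[0]
        catalog = extract_introns(cohort.models[sp], cohort.genomes[sp])
        pairs = intron_similarity_screen(catalog)
        fam_seq = [s for s, c in
                   __import__("collections").Counter(
                       ch.sequence for ch in
                       cohort.truth.intron_characters.values()).items()
                   if c > 1][0]
        members = {r.key for r in catalog if r.sequence == fam_seq}
        assert len(members) == 4
        partner_count = {m: 0 for m in members}
        for _, row in pairs.iterrows():
            if row["intron_a"] in members and row["intron_b"] in members:
                partner_count[row["intron_a"]] += 1
                partner_count[row["intron_b"]] += 1
        assert all(v == 3 for v in partner_count.values())
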