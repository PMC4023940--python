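"""Generators: planted-SSR genomes, contaminated reads, genotype tables."""

import numpy as np
import pytest

import ssrforge as sf
from ssrforge.synthetic_data import POPULATION_CODES, write_truth_labels


class TestMakeGenome:
    def test_planted_ssrs_appear_verbatim_and_truth_is_exact(self, planted_genome):
        contigs, truth = planted_genome
        seqs = {c.id: c.sequence for c in contigs}
        for locus in truth:
            tract = seqs[locus.contig_id][locus.start - 1 : locus.end]
            assert tract == locus.motif * locus.repeat_count
        assert sf.scan_contigs(contigs) == sorted(truth, key=lambda l: (l.contig_id, l.start))

    def test_zero_planted_ssrs_scan_clean(self):
        contigs, truth = sf.make_genome(sf.GenomeSpec(n_contigs=3, seed=3))
        assert truth == []
        assert sf.scan_contigs(contigs) == []

    def test_background_gc_near_target(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=3, gc_target=0.365, seed=4))
        for c in contigs:
            gc = (c.sequence.count("G") + c.sequence.count("C")) / len(c)
            assert abs(gc - 0.365) <= 0.02

    def test_same_seed_is_byte_identical(self):
        spec = dict(n_contigs=2, planted_ssrs=[("AC", 7, 0, 400)], seed=9)
        a, _ = sf.make_genome(sf.GenomeSpec(**spec))
        b, _ = sf.make_genome(sf.GenomeSpec(**spec))
        assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]

    @pytest.mark.parametrize(
        "planted",
        [
            [("AC", 8, 0, 100)],  # violates 250 bp edge margin
            [("AC", 8, 0, 500), ("AG", 8, 0, 505)],  # overlapping tracts
            [("ATAT", 5, 0, 500)],  # non-primitive motif
            [("AC", 8, 5, 500)],  # contig index out of range
        ],
    )
    def test_infeasible_specs_rejected_with_diagnostic(self, planted):
        with pytest.raises(ValueError):
            sf.GenomeSpec(n_contigs=2, planted_ssrs=planted, seed=0)


class TestSimulateReads:
    def test_total_bases_match_requested_depth(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=4, min_len=2400, max_len=2600, seed=5))
        genome = sum(len(c) for c in contigs)
        res = sf.simulate_reads(contigs, depth=20, read_len=150, seed=6)
        total_bases = sum(len(p.mate1.sequence) + len(p.mate2.sequence) for p in res.pairs)
        assert total_bases == pytest.approx(20 * genome, rel=0.05)

    def test_no_contamination_all_host_labels(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=2, seed=7))
        res = sf.simulate_reads(contigs, contamination=None, depth=5, seed=8)
        assert set(res.labels) == {"host"}
        assert res.contaminant_contigs == []

    def test_zero_contaminant_fraction_all_host(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=2, seed=7))
        spec = sf.ContaminationSpec(contaminant_fraction_of_reads=0.0)
        res = sf.simulate_reads(contigs, spec, depth=5, seed=8)
        assert set(res.labels) == {"host"}

    def test_same_seed_identical_output(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=2, seed=7))
        r1 = sf.simulate_reads(contigs, sf.ContaminationSpec(), depth=5, seed=9)
        r2 = sf.simulate_reads(contigs, sf.ContaminationSpec(), depth=5, seed=9)
        assert [(p.mate1.sequence, p.mate2.sequence) for p in r1.pairs] == [
            (p.mate1.sequence, p.mate2.sequence) for p in r2.pairs
        ]
        assert r1.labels == r2.labels

    def test_read_longer_than_contig_errors_naming_contig(self):
        with pytest.raises(ValueError, match="tiny"):
            sf.simulate_reads([sf.Contig("tiny", "ACGT" * 10)], read_len=150, depth=5, seed=0)

    def test_contaminant_depth_multiplier_sets_elevated_depth(self, contaminated_reads):
        host = np.mean(list(contaminated_reads.host_depths.values()))
        endo = np.mean(list(contaminated_reads.contaminant_depths.values()))
        assert endo / host == pytest.approx(5.0, rel=0.15)

    def test_phred33_qualities_and_error_free_profile(self, contaminated_reads):
        pair = contaminated_reads.pairs[0]
        assert all(q == 40 for q in pair.mate1.qualities)

    def test_gc_margin_validation(self):
        contigs, _ = sf.make_genome(sf.GenomeSpec(n_contigs=2, seed=7))
        with pytest.raises(ValueError, match="GC"):
            sf.simulate_reads(contigs, sf.ContaminationSpec(contaminant_gc=0.37), depth=5, seed=0)

    def test_truth_label_sidecar(self, contaminated_reads, tmp_path):
        path = tmp_path / "labels.tsv"
        write_truth_labels(contaminated_reads, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "pair\tlabel"
        assert len(lines) - 1 == len(contaminated_reads.pairs)
        assert {l.split("\t")[1] for l in lines[1:]} == {"host", "contaminant"}


class TestSimulateGenotypes:
    def test_fst_zero_frequencies_converge_to_ancestral(self):
        """Law-of-large-numbers check: with Fst=0 and many individuals the
        observed per-population frequencies approach the ancestral ones."""
        model = sf.PopulationModel(
            n_populations=2, n_individuals_per_pop=2000, n_loci=4,
            n_alleles_per_locus=4, fst=0.0, seed=31,
        )
        table, ancestral, _ = sf.simulate_genotypes(model)
        freqs = sf.popgen.allele_frequencies(table, pooled=False)
        for locus in table.loci:
            for pop in table.populations:
                obs = freqs[locus][pop]
                for a, p_true in enumerate(ancestral[locus], start=1):
                    assert abs(obs.get(a, 0.0) - p_true) < 0.02

    def test_single_allele_all_homozygous(self):
        model = sf.PopulationModel(
            n_populations=2, n_individuals_per_pop=10, n_loci=3,
            n_alleles_per_locus=1, seed=32,
        )
        table, _, _ = sf.simulate_genotypes(model)
        for locus in table.loci:
            s = sf.locus_stats(table, locus)
            assert s.ho == 0.0 and s.na == 1

    def test_same_seed_identical_table(self):
        model = sf.PopulationModel(n_populations=3, n_individuals_per_pop=5, n_loci=4, seed=33)
        t1, _, _ = sf.simulate_genotypes(model)
        t2, _, _ = sf.simulate_genotypes(model)
        assert t1.calls == t2.calls

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            sf.PopulationModel(fst=1.0)
        with pytest.raises(ValueError):
            sf.PopulationModel(fst=-0.1)

    def test_default_design_uses_survey_codes(self):
        model = sf.PopulationModel()
        assert model.n_populations == 18
        assert model.population_labels() == POPULATION_CODES

    def test_pooled_he_matches_ancestral_gene_diversity(self):
        """Pooled expected heterozygosity tracks 1 - sum(p_bar^2) of the true
        ancestral frequencies (Fst=0, 200 individuals/pop, tolerance 0.03)."""
        model = sf.PopulationModel(
            n_populations=3, n_individuals_per_pop=200, n_loci=6,
            n_alleles_per_locus=5, fst=0.0, seed=34,
        )
        table, ancestral, _ = sf.simulate_genotypes(model)
        for locus in table.loci:
            expected = 1.0 - float(np.sum(ancestral[locus] ** 2))
            s = sf.locus_stats(table, locus, unbiased=False)
            assert abs(s.he - expected) < 0.03
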