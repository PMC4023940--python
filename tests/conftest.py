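import pytest

import ssrforge as sf


@pytest.fixture(scope="session")
def planted_genome():
    """Small host genome with one planted SSR per motif size 2-6."""
    spec = sf.GenomeSpec(
        n_contigs=5,
        min_len=2000,
        max_len=3000,
        planted_ssrs=[
            ("AC", 8, 0, 500),
            ("AAG", 6, 1, 700),
            ("ATCG", 5, 2, 900),
            ("AACGT", 5, 3, 600),
            ("AACGTC", 5, 4, 800),
        ],
        seed=11,
    )
    return sf.make_genome(spec)


@pytest.fixture(scope="session")
def contaminated_reads(planted_genome):
    """Error-free contaminated read set with truth labels."""
    contigs, _ = planted_genome
    return sf.simulate_reads(
        contigs,
        sf.ContaminationSpec(),
        error_profile=sf.ErrorProfile.error_free(),
        seed=12,
    )


@pytest.fixture(scope="session")
def genotype_table():
    model = sf.PopulationModel(
        n_populations=6, n_individuals_per_pop=20, n_loci=8, n_alleles_per_locus=5,
        fst=0.1, seed=13,
    )
    table, ancestral, per_pop = sf.simulate_genotypes(model)
    return table, ancestral, per_pop
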