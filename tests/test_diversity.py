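import itertools
import math

import numpy as np
import pytest

import landgen as lg
from landgen.diversity import _rarefied_richness

from conftest import genotypes_from_lists


def _single_pop(calls):
    return genotypes_from_lists({"p1": calls})


class TestAlleleFrequencies:
    def test_two_individuals(self):
        g, m = _single_pop([[(100, 100)], [(100, 102)]])
        freqs = lg.allele_frequencies(g, m)
        by_allele = freqs.set_index("allele")["frequency"]
        assert by_allele[100] == 0.75
        assert by_allele[102] == 0.25

    def test_all_missing_flagged_undefined(self):
        g, m = _single_pop([[(0, 0)], [(0, 0)]])
        freqs = lg.allele_frequencies(g, m)
        assert not freqs["defined"].any()

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        calls = [[(100 + 2 * rng.integers(0, 5), 100 + 2 * rng.integers(0, 5))
                  for _ in range(3)] for _ in range(20)]
        g, m = _single_pop(calls)
        freqs = lg.allele_frequencies(g, m)
        sums = freqs.groupby("locus")["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestHeterozygosity:
    def test_ho_extremes(self):
        g, m = _single_pop([[(100, 100)], [(102, 102)]])
        assert lg.observed_heterozygosity(g, m).loc["p1", "L1"] == 0.0
        g, m = _single_pop([[(100, 102)], [(100, 104)]])
        assert lg.observed_heterozygosity(g, m).loc["p1", "L1"] == 1.0

    def test_he_unbiased_hand_value(self):
        # 2 individuals, gene copies A,A,A,B: 1-(0.75^2+0.25^2)=0.375; x(4/3)=0.5
        g, m = _single_pop([[(100, 100)], [(100, 102)]])
        assert lg.expected_heterozygosity(g, m).loc["p1", "L1"] == pytest.approx(0.5)

    def test_he_monomorphic_zero(self):
        g, m = _single_pop([[(100, 100)], [(100, 100)]])
        assert lg.expected_heterozygosity(g, m).loc["p1", "L1"] == 0.0

    def test_he_undefined_below_two_genes(self):
        g, m = _single_pop([[(100, 100)], [(0, 0)]])
        # one individual genotyped -> 2 genes, defined; zero genotyped -> NaN
        g2, m2 = _single_pop([[(0, 0)], [(0, 0)]])
        assert np.isnan(lg.expected_heterozygosity(g2, m2).loc["p1", "L1"])

    def test_he_at_least_biased_estimate(self):
        rng = np.random.default_rng(1)
        calls = [[(100 + 2 * rng.integers(0, 8), 100 + 2 * rng.integers(0, 8))]
                 for _ in range(15)]
        g, m = _single_pop(calls)
        he = lg.expected_heterozygosity(g, m).loc["p1", "L1"]
        alleles = np.array([a for row in calls for a in row[0]])
        _, counts = np.unique(alleles, return_counts=True)
        biased = 1 - ((counts / counts.sum()) ** 2).sum()
        assert he >= biased - 1e-12


class TestRarefiedRichness:
    def test_enumeration_oracle_small_counts(self):
        # counts {A:2, B:2}, g=2: average distinct alleles over all C(4,2)
        # subsamples of gene copies
        genes = ["A", "A", "B", "B"]
        subs = list(itertools.combinations(range(4), 2))
        expected = np.mean([len({genes[i] for i in s}) for s in subs])
        assert expected == pytest.approx(5 / 3)
        assert _rarefied_richness({1: 2, 2: 2}, 2) == pytest.approx(expected)

    @pytest.mark.parametrize("counts", [{1: 5, 2: 3}, {1: 2, 2: 2, 3: 6}])
    def test_enumeration_oracle_general(self, counts):
        genes = [a for a, c in counts.items() for _ in range(c)]
        n = len(genes)
        for g_genes in (1, 2, 4):
            subs = itertools.combinations(range(n), g_genes)
            expected = np.mean([len({genes[i] for i in s}) for s in subs])
            assert _rarefied_richness(counts, g_genes) == pytest.approx(expected)

    def test_full_sample_equals_allele_count(self):
        g, m = _single_pop([[(100, 102)], [(104, 104)]])
        ar = lg.rarefied_allelic_richness(g, m, g_genes=4)
        assert ar.loc["p1", "L1"] == pytest.approx(3.0)

    def test_single_gene_polymorphic_is_one(self):
        g, m = _single_pop([[(100, 102)], [(104, 104)]])
        ar = lg.rarefied_allelic_richness(g, m, g_genes=1)
        assert ar.loc["p1", "L1"] == pytest.approx(1.0)

    def test_monotone_in_subsample_size(self):
        counts = {1: 7, 2: 2, 3: 1}
        values = [_rarefied_richness(counts, g) for g in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


class TestPrivateAllelesAndGW:
    def test_identical_populations_no_private(self):
        calls = [[(100, 102)], [(102, 102)]]
        g, m = genotypes_from_lists({"p1": calls, "p2": calls})
        assert (lg.private_alleles(g, m) == 0).all()

    def test_private_allele_counted_once(self):
        g, m = genotypes_from_lists({
            "W1": [[(100, 110)]],  # 110 only here
            "W2": [[(100, 100)]],
        })
        pa = lg.private_alleles(g, m)
        assert pa["W1"] == 1 and pa["W2"] == 0

    def test_private_bounded_by_total(self):
        sc = lg.make_scenario("stepping_stone", seed=2, n_pops=4, sizes=[10] * 4)
        g, m = lg.simulate_dataset(sc)
        total = len(set(
            (j, a) for j in range(g.n_loci)
            for a in g.calls[:, j, :].ravel() if a != 0
        ))
        assert lg.private_alleles(g, m).sum() <= total

    def test_gw_contiguous_ladder_is_one(self):
        g, m = _single_pop([[(120, 122)], [(124, 122)]])
        assert lg.garza_williamson(g, m, 2).loc["p1", "L1"] == pytest.approx(1.0)

    def test_gw_two_allele_gap(self):
        # repeat counts {10, 12}: M = 2 / (2 + 1)
        g, m = _single_pop([[(120, 124)], [(120, 120)]])
        assert lg.garza_williamson(g, m, 2).loc["p1", "L1"] == pytest.approx(2 / 3)

    def test_gw_off_ladder_rejected(self):
        g, m = _single_pop([[(120, 123)]])
        with pytest.raises(lg.ValidationError, match="ladder"):
            lg.garza_williamson(g, m, 2)


class TestFis:
    def test_all_heterozygotes_minus_one(self):
        g, m = _single_pop([[(100, 102)] for _ in range(10)])
        res = lg.fis_bootstrap(g, m, n_boot=100, seed=0)
        assert res.loc["p1", "fis"] == pytest.approx(-1.0)

    def test_hwe_population_near_zero(self):
        # 500 individuals, 10 loci simulated under HWE at p=0.5
        rng = np.random.default_rng(42)
        calls = [
            [tuple(100 + 2 * rng.integers(0, 2, size=2)) for _ in range(10)]
            for _ in range(500)
        ]
        g, m = _single_pop(calls)
        res = lg.fis_bootstrap(g, m, n_boot=200, seed=0)
        assert abs(res.loc["p1", "fis"]) < 0.05
        assert res.loc["p1", "ci_low"] < 0 < res.loc["p1", "ci_high"]
        assert res.loc["p1", "p_value"] > 0.05

    def test_single_locus_no_ci(self):
        g, m = _single_pop([[(100, 102)], [(100, 100)], [(102, 102)]])
        res = lg.fis_bootstrap(g, m, n_boot=50, seed=0)
        assert np.isfinite(res.loc["p1", "fis"])
        assert np.isnan(res.loc["p1", "ci_low"])


class TestDiversityTable:
    def test_study_shaped_summary_shape_and_ranges(self):
        sc = lg.make_scenario("study_shaped", seed=5)
        g, m = lg.simulate_dataset(sc)
        table = lg.diversity_table(g, m, n_boot=100, seed=0)
        assert len(table) == 15
        for col in ("mean_ho", "mean_he"):
            assert table[col].between(0, 1).all()
        assert table["fis"].between(-1, 1).all()
        assert (table["garza_williamson"].dropna() <= 1).all()
        assert (table["private_alleles"] >= 0).all()
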