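from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

import msprivtime as mp
from msprivtime.diversity_stats import StatsError, UndefinedStatistic

from conftest import build_dataset, female, male, random_female_dataset
from oracles import (
    oracle_allelic_richness_exhaustive,
    oracle_gene_diversity,
    oracle_haplotype_diversity,
    oracle_nucleotide_diversity,
    oracle_weir_cockerham,
)


class TestHeterozygosity:
    def test_all_heterozygous_females(self):
        ds = build_dataset(
            [
                (female("f1"), {"L1": (1, 2)}),
                (female("f2"), {"L1": (1, 2)}),
            ]
        )
        h_o, _ = mp.heterozygosity(ds, "Ishigaki", "L1")
        assert h_o == 1.0

    def test_all_homozygous_monomorphic(self):
        ds = build_dataset(
            [
                (female("f1"), {"L1": (1, 1)}),
                (female("f2"), {"L1": (1, 1)}),
            ]
        )
        h_o, h_e = mp.heterozygosity(ds, "Ishigaki", "L1")
        assert (h_o, h_e) == (0.0, 0.0)

    def test_five_female_fixture_matches_hand_computation(self):
        genos = [(1, 2), (1, 1), (2, 3), (3, 3), (1, 3)]
        ds = build_dataset(
            [(female(f"f{i}"), {"L1": g}) for i, g in enumerate(genos)]
        )
        h_o, h_e = mp.heterozygosity(ds, "Ishigaki", "L1")
        # hand: 3 of 5 heterozygous; copies 4x1, 2x2, 4x3 of 10
        assert h_o == 3 / 5
        sum_p2 = (4 / 10) ** 2 + (2 / 10) ** 2 + (4 / 10) ** 2
        assert h_e == pytest.approx((10 / 9) * (1 - sum_p2), rel=1e-12)

    def test_males_are_excluded(self):
        ds = build_dataset(
            [
                (female("f1"), {"L1": (1, 1)}),
                (female("f2"), {"L1": (1, 2)}),
                (male("m1", "Ishigaki"), {"L1": (9,)}),
            ]
        )
        h_o, h_e = mp.heterozygosity(ds, "Ishigaki", "L1")
        assert h_o == 0.5  # the male's allele 9 plays no part
        # female copies only: 3x allele1, 1x allele2 of 4
        assert h_e == pytest.approx((4 / 3) * (1 - (9 + 1) / 16), rel=1e-12)

    def test_no_female_data_is_flagged_not_zero(self):
        ds = build_dataset([(male("m1", "Okinawa"), {"L1": (9,)})])
        with pytest.raises(UndefinedStatistic):
            mp.heterozygosity(ds, "Okinawa", "L1")


class TestGeneDiversity:
    def test_monomorphic_is_zero(self):
        ds = build_dataset(
            [(female("f1"), {"L1": (5, 5)}), (male("m1", "Ishigaki"), {"L1": (5,)})]
        )
        assert mp.gene_diversity(ds, "Ishigaki", "L1") == 0.0

    def test_two_distinct_copies_give_one(self):
        ds = build_dataset([(female("f1"), {"L1": (5, 8)})])
        assert mp.gene_diversity(ds, "Ishigaki", "L1") == pytest.approx(1.0)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            ds = random_female_dataset(rng, n_pops=1, n_females=int(rng.integers(2, 9)))
            for locus in ds.loci:
                copies = ds.gene_copies(ds.samples, locus)
                assert mp.gene_diversity(ds, "pop0", locus) == pytest.approx(
                    oracle_gene_diversity(copies), rel=1e-12
                )

    def test_males_contribute_single_copies(self):
        ds = build_dataset(
            [(female("f1"), {"L1": (1, 2)}), (male("m1", "Ishigaki"), {"L1": (3,)})]
        )
        copies = [1, 2, 3]
        assert mp.gene_diversity(ds, "Ishigaki", "L1") == pytest.approx(
            oracle_gene_diversity(copies)
        )


class TestAllelicRichness:
    def _balanced_ds(self):
        rows = [(female(f"f{i}"), {"L1": (1, 1)}) for i in range(3)]
        rows += [(female(f"g{i}"), {"L1": (2, 2)}) for i in range(2)]
        rows.append((male("m0", "Ishigaki"), {"L1": (2,)}))
        return build_dataset(rows)  # copies: 6x1? no: 6 of allele1? 3 females->6, 2->4+1

    def test_g_equals_n_returns_observed_count(self):
        ds = self._balanced_ds()
        n = len(ds.gene_copies(ds.samples, "L1"))
        assert mp.allelic_richness(ds, "Ishigaki", "L1", n) == pytest.approx(2.0)

    def test_g_one_is_exactly_one(self):
        ds = self._balanced_ds()
        assert mp.allelic_richness(ds, "Ishigaki", "L1", 1) == pytest.approx(1.0)

    def test_five_five_split_matches_exhaustive_enumeration(self):
        # 10 copies, two alleles 5/5, g=2: oracle enumerates all C(10,2) pairs
        rows = [(female(f"f{i}"), {"L1": (1, 1)}) for i in range(2)]
        rows.append((female("fx"), {"L1": (1, 2)}))
        rows += [(female(f"g{i}"), {"L1": (2, 2)}) for i in range(2)]
        ds = build_dataset(rows)
        copies = ds.gene_copies(ds.samples, "L1")
        assert sorted(copies).count(1) == 5 and sorted(copies).count(2) == 5
        expected = oracle_allelic_richness_exhaustive(copies, 2)
        got = mp.allelic_richness(ds, "Ishigaki", "L1", 2)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(2 * (1 - 10 / 45), rel=1e-12)

    def test_random_fixtures_match_exhaustive_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            ds = random_female_dataset(
                rng, n_pops=1, n_females=int(rng.integers(2, 6)), n_loci=2
            )
            for locus in ds.loci:
                copies = ds.gene_copies(ds.samples, locus)
                g = int(rng.integers(1, len(copies) + 1))
                assert mp.allelic_richness(ds, "pop0", locus, g) == pytest.approx(
                    oracle_allelic_richness_exhaustive(copies, g), rel=1e-10
                )

    def test_monotone_in_g(self):
        rng = np.random.default_rng(31)
        ds = random_female_dataset(rng, n_pops=1, n_females=6, n_loci=1)
        copies = ds.gene_copies(ds.samples, "L0")
        values = [
            mp.allelic_richness(ds, "pop0", "L0", g)
            for g in range(1, len(copies) + 1)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_g_beyond_copies_rejected(self):
        ds = self._balanced_ds()
        with pytest.raises(StatsError, match="exceeds"):
            mp.allelic_richness(ds, "Ishigaki", "L1", 99)


class TestWeirCockerham:
    def test_all_heterozygotes_give_f_minus_one(self):
        ds = build_dataset(
            [(female(f"f{i}"), {"L1": (1, 2)}) for i in range(6)]
        )
        res = mp.weir_cockerham(ds, populations=["Ishigaki"])
        assert res.f_overall == pytest.approx(-1.0)

    def test_two_alleles_no_heterozygote_gives_f_one(self):
        rows = [(female(f"f{i}"), {"L1": (1, 1)}) for i in range(3)]
        rows += [(female(f"g{i}"), {"L1": (2, 2)}) for i in range(3)]
        res = mp.weir_cockerham(build_dataset(rows), populations=["Ishigaki"])
        assert res.f_overall == pytest.approx(1.0)

    def test_random_two_pop_fixtures_match_component_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(25):
            ds = random_female_dataset(
                rng,
                n_pops=2,
                n_females=int(rng.integers(3, 8)),
                n_loci=int(rng.integers(1, 4)),
            )
            res = mp.weir_cockerham(ds, populations=["pop0", "pop1"])
            # multi-locus: oracle sums components over loci
            SA = SB = SC = 0.0
            for locus in ds.loci:
                pops = [
                    [
                        tuple(ds.get_call(s.sample_id, locus))
                        for s in ds.select(population=p, sex="female")
                        if ds.get_call(s.sample_id, locus) is not None
                    ]
                    for p in ("pop0", "pop1")
                ]
                f_l, t_l = oracle_weir_cockerham(pops)
                if res.f_per_locus[locus] is not None and f_l is not None:
                    assert res.f_per_locus[locus] == pytest.approx(f_l, rel=1e-10)
                if res.theta_per_locus[locus] is not None and t_l is not None:
                    assert res.theta_per_locus[locus] == pytest.approx(t_l, rel=1e-10)

    def test_theta_near_zero_for_split_halves_of_one_population(self):
        rng = np.random.default_rng(43)
        genos = [tuple(int(a) for a in rng.integers(1, 5, size=2)) for _ in range(40)]
        rows = [
            (
                mp.SampleMeta(f"s{i}", "popA" if i % 2 == 0 else "popB", "native", "female"),
                {"L1": g},
            )
            for i, g in enumerate(genos)
        ]
        res = mp.weir_cockerham(build_dataset(rows), populations=["popA", "popB"])
        assert abs(res.theta_overall) < 0.08

    def test_single_diploid_individual_is_undefined(self):
        ds = build_dataset([(female("f1"), {"L1": (1, 2)})])
        with pytest.raises(UndefinedStatistic):
            mp.weir_cockerham(ds, populations=["Ishigaki"])

    def test_multilocus_is_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(47)
        ds = random_female_dataset(rng, n_pops=1, n_females=8, n_loci=3)
        res = mp.weir_cockerham(ds, populations=["pop0"])
        per_locus = [v for v in res.f_per_locus.values() if v is not None]
        SB = sum(res.components[l][1] for l in res.components)
        SC = sum(res.components[l][2] for l in res.components)
        assert res.f_overall == pytest.approx(1 - SC / (SB + SC), rel=1e-12)
        assert res.f_overall != pytest.approx(float(np.mean(per_locus)), abs=1e-6)


class TestHWEDeficitTest:
    def test_monomorphic_locus_returns_one(self):
        ds = build_dataset(
            [(female(f"f{i}"), {"L1": (1, 1)}) for i in range(5)]
        )
        assert mp.hwe_deficit_test(ds, "Ishigaki", "L1", 999, 0) == 1.0

    def test_strong_deficit_is_significant(self):
        rows = [(female(f"f{i}"), {"L1": (1, 1)}) for i in range(10)]
        rows += [(female(f"g{i}"), {"L1": (2, 2)}) for i in range(10)]
        p = mp.hwe_deficit_test(build_dataset(rows), "Ishigaki", "L1", 9999, 1)
        assert p < 0.05

    def test_null_p_values_roughly_uniform(self):
        # random-mating fixtures: p ~ U(0,1) up to permutation discreteness;
        # fixtures are large so the null statistic is near-continuous
        rng = np.random.default_rng(53)
        pvals = []
        for _ in range(120):
            freqs = rng.dirichlet(np.full(6, 1.5))
            copies = rng.choice(np.arange(1, 7), size=200, p=freqs)
            rows = [
                (female(f"f{i}"), {"L1": (int(copies[2 * i]), int(copies[2 * i + 1]))})
                for i in range(100)
            ]
            pvals.append(
                mp.hwe_deficit_test(build_dataset(rows), "Ishigaki", "L1", 999, rng)
            )
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestMtDna:
    def test_identical_sequences_collapse_to_one(self):
        aln = mp.HaplotypeAlignment(
            ids=[f"s{i}" for i in range(10)], seqs=["ACGT"] * 10
        )
        summary = mp.collapse_haplotypes(aln)
        assert summary.n_haplotypes == 1
        assert summary.haplotype_diversity == 0.0
        assert summary.nucleotide_diversity == 0.0

    def test_three_sequences_two_segregating_sites(self):
        aln = mp.HaplotypeAlignment(ids=["a", "b", "c"], seqs=["AAA", "AAT", "ATT"])
        summary = mp.collapse_haplotypes(aln)
        assert summary.n_haplotypes == 3
        assert summary.n_segregating_sites == 2

    def test_collapse_matches_set_of_strings_oracle(self):
        rng = np.random.default_rng(59)
        result = mp.simulate(
            mp.SimConfig(
                seed=59, n_loci=5, t_burnin=10, t_split=30, n_broods=6,
                n_broods_native=8, n_sample=5, n_sample_native=6, mu_mt=5e-3,
            )
        )
        aln = result.native_mt
        summary = mp.collapse_haplotypes(aln)
        assert summary.n_haplotypes == len(set(aln.seqs))

    def test_two_individuals_distinct_haplotypes_give_hd_one(self):
        aln = mp.HaplotypeAlignment(ids=["a", "b"], seqs=["AAAA", "AAAT"])
        assert mp.collapse_haplotypes(aln).haplotype_diversity == pytest.approx(1.0)

    def test_hand_computed_hd_for_7_4_3(self):
        seqs = ["AAA"] * 7 + ["AAT"] * 4 + ["ATT"] * 3
        aln = mp.HaplotypeAlignment(ids=[f"s{i}" for i in range(14)], seqs=seqs)
        hd = mp.collapse_haplotypes(aln).haplotype_diversity
        # hand: (14/13)(1 - (49+16+9)/196)
        assert hd == pytest.approx((14 / 13) * (1 - 74 / 196), rel=1e-12)
        assert hd == pytest.approx(oracle_haplotype_diversity(seqs), rel=1e-12)

    def test_single_site_difference_over_532(self):
        seq = "ACGT" * 133
        other = "T" + seq[1:]
        aln = mp.HaplotypeAlignment(ids=["a", "b"], seqs=[seq, other])
        assert mp.nucleotide_diversity(aln) == pytest.approx(1 / 532, rel=1e-12)

    def test_pi_matches_all_pairs_oracle_with_ambiguity(self):
        seqs = ["ACGTAC", "ACGTAT", "ACGNAT", "AC-TAT", "TCGTAT"]
        aln = mp.HaplotypeAlignment(ids=[f"s{i}" for i in range(5)], seqs=seqs)
        assert mp.nucleotide_diversity(aln) == pytest.approx(
            oracle_nucleotide_diversity(seqs), rel=1e-12
        )

    def test_hd_and_pi_invariant_under_reordering(self):
        rng = np.random.default_rng(61)
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(6)]
        aln1 = mp.HaplotypeAlignment(ids=[f"s{i}" for i in range(6)], seqs=seqs)
        order = rng.permutation(6)
        aln2 = mp.HaplotypeAlignment(
            ids=[f"s{i}" for i in order], seqs=[seqs[i] for i in order]
        )
        assert mp.nucleotide_diversity(aln1) == pytest.approx(
            mp.nucleotide_diversity(aln2)
        )
        s1, s2 = mp.collapse_haplotypes(aln1), mp.collapse_haplotypes(aln2)
        assert s1.haplotype_diversity == pytest.approx(s2.haplotype_diversity)

    def test_pairwise_matrix_symmetry_and_hand_case(self, small_alignment):
        mat = mp.pairwise_differences(small_alignment)
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diag(mat) == 0)
        assert mat[0, 1] == 0  # identical pair
        assert mat[0, 2] == 1 and mat[0, 3] == 2 and mat[2, 3] == 1

    def test_min_between_clusters(self, small_alignment):
        assert (
            mp.min_between_clusters(small_alignment, ["a", "b"], ["c", "d"]) == 1
        )
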