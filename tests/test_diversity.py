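"""Discriminatory power, per-locus diversity statistics and linkage."""

import itertools
import math

import numpy as np
import pytest

from mlstpop.diversity import (
    LocusAlignment,
    SaturationError,
    _codon_pair_diffs,
    allele_count_per_locus,
    dnds_alignment,
    gc_content,
    index_of_association,
    mean_pairwise_differences,
    nei_gojobori_pair,
    nucleotide_diversity,
    polymorphic_sites,
    simpson_hunter_gaston,
    tajimas_d,
)
from conftest import random_alignment
from oracles import (
    codon_path_counts,
    hunter_gaston_exact,
    ia_enumerate,
    ng86_pair,
    pairwise_pi,
    polymorphic_sites_scan,
    tajima_d_direct,
)


class TestHunterGaston:
    def test_forced_extremes(self):
        assert simpson_hunter_gaston([1] * 10).d == 1.0
        assert simpson_hunter_gaston([10]).d == 0.0

    def test_reconstructed_full_spectrum(self):
        # three STs of 4, four of 3, three of 2, fifteen unique: N = 45
        counts = [4] * 3 + [3] * 4 + [2] * 3 + [1] * 15
        res = simpson_hunter_gaston(counts)
        assert res.n == 45
        assert res.d == pytest.approx(1 - 66 / 1980, abs=1e-12)
        assert res.ci_low < res.d < res.ci_high

    def test_matches_exact_formula_and_order_invariance(self, rng):
        for _ in range(20):
            counts = [int(c) for c in rng.integers(1, 9, size=rng.integers(2, 12))]
            res = simpson_hunter_gaston(counts)
            assert res.d == pytest.approx(float(hunter_gaston_exact(counts)), abs=1e-12)
            shuffled = list(counts)
            rng.shuffle(shuffled)
            assert simpson_hunter_gaston(shuffled).d == res.d

    def test_too_few_isolates_rejected(self):
        with pytest.raises(ValueError):
            simpson_hunter_gaston([1])


class TestAlleleCounts:
    def test_fixture_counts_match_printed_report(self, records):
        counts = allele_count_per_locus(records)
        assert counts["pyrG"] == 7
        assert counts["rpoB"] == 9
        assert counts["uvrC"] == 10
        assert counts["carB"] == 13
        assert counts["murC"] == 6
        # loci whose printed totals include isolates absent from the
        # printed profile matrix can only be bounded from below
        assert counts["groEL"] <= 7
        assert counts["recA"] <= 6
        assert counts["pheS"] <= 5

    def test_single_isolate_gives_one_everywhere(self, records):
        counts = allele_count_per_locus(records[:1])
        assert set(counts.values()) == {1}


class TestAlignmentStatistics:
    def test_identical_sequences_are_monomorphic(self):
        a = LocusAlignment("x", ("ACGT" * 5,) * 4)
        assert polymorphic_sites(a) == 0
        assert nucleotide_diversity(a) == 0.0

    def test_constructed_counts(self):
        a = LocusAlignment("x", ("AAAAAAAAAA", "AATAAGAACA"))
        assert polymorphic_sites(a) == 3
        assert nucleotide_diversity(a) == pytest.approx(0.3)

    def test_columns_with_ambiguity_dropped(self):
        a = LocusAlignment("x", ("ANGTA", "ACGTA", "ACGTT"))
        # column 2 (N) excluded entirely; column 5 segregates
        assert polymorphic_sites(a) == 1
        assert a.clean_columns() == [0, 2, 3, 4]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            LocusAlignment("x", ("ACGT", "ACG"))

    @pytest.mark.parametrize("seq,expect", [("GGCC", 1.0), ("AATT", 0.0), ("ACGT", 0.5)])
    def test_gc_content(self, seq, expect):
        assert gc_content(LocusAlignment("x", (seq,))) == expect

    def test_random_alignments_match_bruteforce_oracles(self, rng):
        for _ in range(15):
            seqs = random_alignment(rng, int(rng.integers(3, 8)),
                                    int(rng.integers(40, 120)), int(rng.integers(1, 12)))
            a = LocusAlignment("x", tuple(seqs))
            assert polymorphic_sites(a) == polymorphic_sites_scan(seqs)
            assert nucleotide_diversity(a) == pytest.approx(pairwise_pi(seqs), abs=1e-12)

    def test_two_sequences_one_difference(self):
        a = LocusAlignment("x", ("A" * 100, "A" * 99 + "T"))
        assert nucleotide_diversity(a) == pytest.approx(0.01)


class TestTajimasD:
    def test_monomorphic_returns_sentinel(self):
        assert tajimas_d(LocusAlignment("x", ("ACGT" * 10,) * 5)) is None

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(LocusAlignment("x", ("ACGT", "ACGA", "ACGC")))

    def test_four_sequences_single_singleton_closed_form(self):
        seqs = ("A" * 50, "A" * 50, "A" * 50, "A" * 49 + "T")
        d = tajimas_d(LocusAlignment("x", seqs))
        # khat = 3/6 = 0.5; S = 1; a1 = 11/6; D = (0.5 - 6/11)/sqrt(e1)
        n, a1 = 4, 11 / 6
        b1 = (n + 1) / (3 * (n - 1))
        c1 = b1 - 1 / a1
        e1 = c1 / a1
        assert d == pytest.approx((0.5 - 1 / a1) / math.sqrt(e1), abs=1e-12)
        assert mean_pairwise_differences(LocusAlignment("x", seqs)) == 0.5

    def test_agrees_with_direct_oracle_on_random_alignments(self, rng):
        checked = 0
        while checked < 12:
            seqs = random_alignment(rng, int(rng.integers(4, 9)),
                                    int(rng.integers(60, 300)), int(rng.integers(1, 15)))
            oracle = tajima_d_direct(seqs)
            if oracle is None:
                continue
            assert tajimas_d(LocusAlignment("x", tuple(seqs))) == pytest.approx(
                oracle, abs=1e-9)
            checked += 1

    def test_neutral_site_sprinkling_centres_near_zero(self, rng):
        # derived-allele counts drawn from the neutral frequency spectrum
        n, s, length = 10, 20, 400
        weights = np.array([1 / i for i in range(1, n)])
        weights /= weights.sum()
        values = []
        for _ in range(200):
            seqs = np.zeros((n, length), dtype="U1")
            seqs[:] = "A"
            pos = rng.choice(length, size=s, replace=False)
            for p in pos:
                count = int(rng.choice(np.arange(1, n), p=weights))
                carriers = rng.choice(n, size=count, replace=False)
                seqs[carriers, p] = "T"
            aln = LocusAlignment("x", tuple("".join(row) for row in seqs))
            values.append(tajimas_d(aln))
        assert abs(np.mean(values)) < 0.5


class TestNeiGojobori:
    def test_identical_sequences(self):
        dn, ds = nei_gojobori_pair("ATGGCT", "ATGGCT")
        assert dn == 0.0 and ds == 0.0

    def test_hand_worked_glycine_example(self):
        dn, ds = nei_gojobori_pair("GGGGGGGGG", "GGAGGGGGG")
        assert dn == 0.0
        assert ds == pytest.approx(-0.75 * math.log(5 / 9), abs=1e-12)

    def test_pathway_average_matches_exhaustive_enumeration(self):
        bases = "ACGT"
        codons = ["".join(c) for c in itertools.product(bases, repeat=3)]
        for c1 in codons:
            for c2 in codons:
                assert _codon_pair_diffs(c1, c2) == pytest.approx(
                    codon_path_counts(c1, c2), abs=1e-12), (c1, c2)

    def test_full_pair_matches_oracle_on_random_genes(self, rng):
        from oracles import GENETIC_CODE

        sense = [c for c, aa in GENETIC_CODE.items() if aa != "*"]
        checked = 0
        while checked < 10:
            n_codons = int(rng.integers(10, 40))
            s1 = "".join(rng.choice(sense, size=n_codons))
            s2 = list(s1)
            for pos in rng.choice(len(s1), size=int(rng.integers(1, 6)), replace=False):
                s2[pos] = rng.choice([b for b in "ACGT" if b != s2[pos]])
            s2 = "".join(s2)
            try:
                mine = nei_gojobori_pair(s1, s2)
            except (SaturationError, ValueError):
                continue  # mutation created an internal stop or saturated pair
            assert mine == pytest.approx(ng86_pair(s1, s2), abs=1e-9)
            checked += 1

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            nei_gojobori_pair("ACGTA", "ACGTA")

    def test_saturation_raises(self):
        # every codon maximally diverged -> p >> 3/4
        with pytest.raises(SaturationError):
            nei_gojobori_pair("AAA" * 10, "GGC" * 10)


class TestDnDsAlignment:
    def test_identical_set(self):
        dn, ds, ratio = dnds_alignment(LocusAlignment("x", ("ATGGCTGCT",) * 3))
        assert (dn, ds, ratio) == (0.0, 0.0, None)

    def test_two_sequences_reduce_to_pair(self):
        s1, s2 = "GGGGGGGGG", "GGAGGGGGG"
        assert dnds_alignment(LocusAlignment("x", (s1, s2)))[:2] == pytest.approx(
            nei_gojobori_pair(s1, s2))

    def test_four_sequences_equal_pairwise_mean_oracle(self, rng):
        while True:
            seqs = random_alignment(rng, 4, 60, 4)
            try:
                dn, ds, _ = dnds_alignment(LocusAlignment("x", tuple(seqs)))
                break
            except ValueError:
                continue
        pairs = [ng86_pair(a.upper(), b.upper())
                 for a, b in itertools.combinations(seqs, 2)]
        assert dn == pytest.approx(np.mean([p[0] for p in pairs]), abs=1e-9)
        assert ds == pytest.approx(np.mean([p[1] for p in pairs]), abs=1e-9)


class TestIndexOfAssociation:
    def test_hand_enumerated_two_locus_example(self):
        res = index_of_association([(1, 1), (1, 1), (2, 2), (2, 2)])
        assert res.v_o == pytest.approx(8 / 9, abs=1e-12)
        assert res.v_e == pytest.approx(0.5, abs=1e-12)
        assert res.ia == pytest.approx(7 / 9, abs=1e-12)
        assert res.s_ia == pytest.approx(7 / 9, abs=1e-12)  # L - 1 = 1

    def test_matches_enumeration_oracle_on_random_profiles(self, rng):
        for _ in range(10):
            profiles = [tuple(int(a) for a in rng.integers(1, 4, size=5))
                        for _ in range(int(rng.integers(4, 12)))]
            try:
                res = index_of_association(profiles)
            except ValueError:
                continue  # monomorphic draw
            assert res.ia == pytest.approx(ia_enumerate(profiles), abs=1e-12)

    def test_single_locus_and_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            index_of_association([(1,), (2,)])
        with pytest.raises(ValueError):
            index_of_association([(1, 1), (1, 1)])

    def test_independent_loci_centre_at_zero(self, rng, records):
        # destroy linkage by permuting each locus column of the observed
        # profiles independently; I_A should centre at ~0
        arr = np.array([r.profile for r in records])
        values = []
        for _ in range(200):
            shuffled = np.column_stack(
                [rng.permutation(arr[:, l]) for l in range(arr.shape[1])])
            values.append(index_of_association(list(map(tuple, shuffled))).ia)
        assert abs(np.mean(values)) < 0.05

    def test_unique_st_unit_collapses_duplicates(self):
        profiles = [(1, 1), (1, 1), (2, 2), (2, 2), (1, 2)]
        res = index_of_association(profiles, unit="unique")
        assert res.ia == pytest.approx(
            ia_enumerate([(1, 1), (2, 2), (1, 2)]), abs=1e-12)

    def test_permutation_p_value_significant_for_perfect_linkage(self):
        profiles = [(i, i, i, i) for i in (1, 1, 1, 2, 2, 2, 3, 3, 3)]
        res = index_of_association(profiles, n_perm=200, seed=11)
        assert res.ia > 0 and res.p_value < 0.05
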