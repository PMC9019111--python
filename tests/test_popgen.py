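"""Allele frequencies, D', diversity and the heterozygote-excess test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kdrhap.popgen import (
    allele_frequencies,
    filter_by_max_frequency,
    het_excess_test,
    lewontin_dprime,
    nucleotide_diversity,
    pin_pis_ratio,
    synonymous_opportunities,
)
from kdrhap.genemodel import CodonEffect

from conftest import make_haps


class TestAlleleFrequencies:
    def test_monomorphic_site_zero_alt(self):
        haps = make_haps(np.zeros((1, 4)))
        table = allele_frequencies(haps)
        assert table.loc[0, "pop1"] == 0.0

    def test_simple_count_ratio(self):
        codes = np.zeros((1, 20))
        codes[0, :3] = 1
        table = allele_frequencies(make_haps(codes))
        assert table.loc[0, "pop1"] == pytest.approx(0.15)

    def test_triallelic_frequencies_sum_to_one(self):
        codes = np.array([[0] * 5 + [1] * 3 + [2] * 2])
        table = allele_frequencies(make_haps(codes))
        assert list(table["pop1"]) == pytest.approx([0.3, 0.2])  # alts only
        # ref + alts sum to 1
        assert 1 - table["pop1"].sum() == pytest.approx(0.5)

    def test_empty_population_flagged_nan(self):
        haps = make_haps(np.zeros((1, 4)))
        table = allele_frequencies(haps, grouping={"empty": np.array([], dtype=int)})
        assert np.isnan(table.loc[0, "empty"])


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "freqs,kept",
        [
            ({"p1": 0.05}, True),  # exactly at threshold: retained
            ({"p1": 0.049}, False),
            ({"p1": 0.003, "p2": 0.30}, True),  # max rule
        ],
    )
    def test_threshold_rule(self, freqs, kept):
        import pandas as pd

        row = dict(chrom="chr1", pos=1, ref="A", alt="T", alt_index=0, **freqs)
        table = pd.DataFrame([row])
        out = filter_by_max_frequency(table, 0.05)
        assert (len(out) == 1) is kept

    def test_invalid_threshold(self):
        import pandas as pd

        with pytest.raises(ValueError):
            filter_by_max_frequency(pd.DataFrame(), 0.0)


class TestDprime:
    def test_perfect_positive_linkage(self):
        # a present only on haplotypes carrying b
        codes = np.array(
            [
                [1, 1, 0, 0, 0, 0],
                [1, 1, 1, 0, 0, 0],
            ]
        )
        res = lewontin_dprime(make_haps(codes), (0, 0), (1, 0))
        assert res.defined
        assert res.Dprime == pytest.approx(1.0)

    def test_never_cooccurring_alleles(self):
        codes = np.array(
            [
                [1, 1, 0, 0, 0, 0],
                [0, 0, 1, 1, 0, 0],
            ]
        )
        res = lewontin_dprime(make_haps(codes), (0, 0), (1, 0))
        assert res.Dprime == pytest.approx(-1.0)

    def test_hand_computed_table(self):
        # AB=4, Ab=1, aB=3, ab=2 -> D=0.05, Dmax=0.15, D'=1/3
        codes = np.array(
            [
                [1] * 5 + [0] * 5,  # A carrier = allele at site 0
                [1] * 4 + [0] * 1 + [1] * 3 + [0] * 2,
            ]
        )
        res = lewontin_dprime(make_haps(codes), (0, 0), (1, 0))
        assert res.D == pytest.approx(0.05)
        assert res.Dmax == pytest.approx(0.15)
        assert res.Dprime == pytest.approx(1 / 3)

    def test_monomorphic_flagged_not_nan(self):
        codes = np.array([[0, 0, 0, 0], [1, 0, 1, 0]])
        res = lewontin_dprime(make_haps(codes), (0, 0), (1, 0))
        assert not res.defined
        assert np.isfinite(res.Dprime)

    def test_label_swap_flips_sign(self):
        """Swapping which allele is 'alt' at one site negates D' (the
        magnitude is invariant)."""
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 2, size=(2, 30))
        haps = make_haps(codes)
        res = lewontin_dprime(haps, (0, 0), (1, 0))
        swapped = make_haps(np.array([1 - codes[0], codes[1]]))
        res2 = lewontin_dprime(swapped, (0, 0), (1, 0))
        assert abs(res.Dprime) == pytest.approx(abs(res2.Dprime))
        if abs(res.Dprime) > 1e-12:
            assert np.sign(res.Dprime) == -np.sign(res2.Dprime)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=100_000))
def test_dprime_bounded_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 2, size=(2, 2 * int(rng.integers(2, 20))))
    haps = make_haps(codes)
    res = lewontin_dprime(haps, (0, 0), (1, 0))
    if res.defined:
        assert -1 - 1e-9 <= res.Dprime <= 1 + 1e-9


class TestDiversity:
    def test_identical_haplotypes_zero_pi(self):
        haps = make_haps(np.zeros((5, 4)))
        res = nucleotide_diversity(haps, np.arange(4), (1, 1001))
        assert res.pi_per_bp == 0.0

    def test_single_pair_single_difference(self):
        haps = make_haps(np.array([[0, 1]]), positions=[500])
        res = nucleotide_diversity(haps, np.arange(2), (1, 1001))
        assert res.pi_per_bp == pytest.approx(0.001)

    def test_two_duplicate_pairs(self):
        # 4 haplotypes: two pairs of duplicates differing at 2 sites,
        # interval 100 bp -> mean diffs 8/6
        codes = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        haps = make_haps(codes, positions=[10, 20])
        res = nucleotide_diversity(haps, np.arange(4), (1, 101))
        assert res.pi_per_bp == pytest.approx((8 / 6) / 100)

    def test_subset_too_small_raises(self):
        haps = make_haps(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            nucleotide_diversity(haps, np.array([0]), (1, 101))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_pairwise_equals_heterozygosity_identity(self, seed):
        """pi from pairwise differences equals the per-site form
        sum 2p(1-p) * n/(n-1) / L (algebraic identity, biallelic)."""
        rng = np.random.default_rng(seed)
        n = 2 * int(rng.integers(2, 15))
        m = int(rng.integers(1, 15))
        codes = rng.integers(0, 2, size=(m, n))
        L = 1000
        haps = make_haps(codes, positions=sorted(rng.choice(np.arange(1, L), m, replace=False).tolist()))
        res = nucleotide_diversity(haps, np.arange(n), (1, L + 1))
        p = codes.mean(axis=1)
        expected = float((2 * p * (1 - p) * n / (n - 1)).sum() / L)
        assert res.pi_per_bp == pytest.approx(expected)


class TestPinPis:
    def test_leucine_codon_opportunity_split(self):
        # CTT: 3 of 9 single-base changes are synonymous -> sites 2:1
        n_nonsyn, n_syn = synonymous_opportunities("CTT")
        assert n_syn == pytest.approx(1.0)  # 3 changes / 3
        assert n_nonsyn == pytest.approx(2.0)  # 6 changes / 3

    def _effects(self, classes):
        return {
            i: CodonEffect("tx", i + 1, "L", "F" if c == "missense" else "L", c)
            for i, c in enumerate(classes)
        }

    def test_no_missense_differences_ratio_zero(self):
        codes = np.array([[0, 0, 0, 0], [0, 1, 0, 1]])
        haps = make_haps(codes)
        effects = self._effects(["missense", "synonymous"])
        res = pin_pis_ratio(haps, np.arange(4), effects, "CTTCTT")
        assert res.pi_n == 0.0
        assert res.ratio == 0.0
        assert res.ratio_defined

    def test_no_synonymous_diversity_flagged(self):
        codes = np.array([[0, 1, 0, 1], [0, 0, 0, 0]])
        haps = make_haps(codes)
        effects = self._effects(["missense", "synonymous"])
        res = pin_pis_ratio(haps, np.arange(4), effects, "CTTCTT")
        assert not res.ratio_defined
        assert res.ratio is None

    def test_disjoint_subsets_with_identical_variation_agree(self):
        codes = np.array([[0, 1, 0, 1], [1, 0, 1, 0]])
        both = np.hstack([codes, codes])
        haps = make_haps(both)
        effects = self._effects(["missense", "synonymous"])
        r1 = pin_pis_ratio(haps, np.arange(4), effects, "CTTCTT")
        r2 = pin_pis_ratio(haps, np.arange(4, 8), effects, "CTTCTT")
        assert r1.ratio == pytest.approx(r2.ratio)


class TestHetExcess:
    def test_zero_observed_het_p_near_one(self):
        res = het_excess_test(40, 40, 20, 50, 0, reps=5000, seed=1)
        assert res.p_value > 0.95

    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            het_excess_test(10, 10, 10, 20, 5, reps=10, seed=0)

    def test_reps_validated(self):
        with pytest.raises(ValueError):
            het_excess_test(10, 10, 20, 20, 5, reps=0, seed=0)

    def test_seed_reproducible(self):
        a = het_excess_test(312, 93, 189, 297, 50, reps=20_000, seed=7)
        b = het_excess_test(312, 93, 189, 297, 50, reps=20_000, seed=7)
        assert a.p_value == b.p_value

    def test_cameroon_like_counts_moderate_p(self):
        """Cohort where the observed compound-heterozygote count sits near
        the Hardy-Weinberg expectation: p should be unremarkable."""
        res = het_excess_test(312, 93, 189, 297, 50, reps=100_000, seed=3)
        assert 0.35 < res.p_value < 0.47

    def test_gabon_like_counts_small_p(self):
        """Cohort with far more compound heterozygotes than HWE predicts."""
        res = het_excess_test(45, 93, 0, 69, 41, reps=100_000, seed=3)
        assert res.p_value < 0.02
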