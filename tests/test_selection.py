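"""Core haplotypes, EHH, window homozygosity, shared lengths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kdrhap.genemodel import CodonEffect
from kdrhap.selection import (
    GeneticMap,
    define_core_haplotypes,
    detection_year_correlation,
    divergence_region_scan,
    ehh_decay,
    haplotype_homozygosity,
    shared_haplotype_lengths,
    window_homozygosity,
)

from conftest import make_haps


class TestCoreHaplotypes:
    def test_identical_cohort_single_core(self):
        haps = make_haps(np.zeros((3, 6)), positions=[10, 20, 30])
        cs = define_core_haplotypes(haps, (5, 35), min_frequency=0.01)
        assert len(cs.cores) == 1
        assert cs.frequencies == [1.0]

    def test_strictly_above_threshold(self):
        # cores A x60, B x39, C x1 out of 100: C sits exactly at 1% and the
        # comparison is strict ("above 1%"), so C is dropped
        codes = np.array([[0] * 60 + [1] * 39 + [2] * 1])
        haps = make_haps(codes, positions=[10])
        cs = define_core_haplotypes(haps, (5, 15), min_frequency=0.01)
        assert len(cs.cores) == 2
        assert cs.frequencies == pytest.approx([0.6, 0.39])

    def test_interval_length_is_end_exclusive(self):
        haps = make_haps(np.zeros((1, 4)), positions=[2_420_500])
        cs = define_core_haplotypes(haps, (2_420_443, 2_426_521))
        assert cs.length == 6_078

    def test_empty_interval_rejected(self):
        haps = make_haps(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            define_core_haplotypes(haps, (10, 10))

    def test_labelling_by_focal_content(self):
        codes = np.array([[1] * 4 + [0] * 8, [0] * 4 + [1] * 4 + [0] * 4])
        haps = make_haps(codes, positions=[10, 12])
        carriage = {
            "F": codes[0] > 0,
            "S": codes[1] > 0,
        }
        cs = define_core_haplotypes(haps, (5, 15), focal_carriage=carriage)
        assert set(cs.labels) == {"F1", "S1", "wt"}


def _brute_force_ehh(codes, carriers, rows):
    """Oracle: explicit prefix-string partitions."""
    out = []
    n = len(carriers)
    for k in range(1, len(rows) + 1):
        strings = {}
        for h in carriers:
            key = tuple(codes[rows[:k], h])
            strings.setdefault(key, 0)
            strings[key] += 1
        num = sum(c * (c - 1) for c in strings.values())
        out.append(num / (n * (n - 1)))
    return np.array(out)


class TestEHH:
    def _core_set(self, haps, core, carriage=None):
        return define_core_haplotypes(haps, core, min_frequency=0.0, focal_carriage=carriage)

    def test_split_two_two_gives_one_third(self):
        # 4 carriers split 2/2 at the first informative site
        codes = np.array([[0, 0, 0, 0], [0, 0, 1, 1]])
        haps = make_haps(codes, positions=[10, 50])
        cs = self._core_set(haps, (5, 15))
        curve = ehh_decay(haps, cs, 0, "downstream", exclude_singletons=False)
        assert curve.ehh[-1] == pytest.approx(1 / 3)

    def test_excluded_only_stretch_keeps_ehh_one(self):
        # the only downstream site is missense -> excluded -> EHH stays 1
        codes = np.array([[0, 0, 0, 0], [0, 0, 1, 1]])
        haps = make_haps(codes, positions=[10, 50])
        effects = {1: CodonEffect("tx", 5, "L", "F", "missense")}
        cs = self._core_set(haps, (5, 15))
        curve = ehh_decay(
            haps, cs, 0, "downstream", effects=effects, exclude_singletons=False
        )
        assert curve.positions.size == 0  # no informative site at all

    def test_identical_carriers_ehh_stays_one(self):
        codes = np.zeros((5, 6))
        codes[0, :] = [0, 0, 0, 1, 1, 1]  # core split
        haps = make_haps(codes, positions=[10, 20, 30, 40, 50])
        cs = self._core_set(haps, (5, 15))
        curve = ehh_decay(haps, cs, 0, "downstream", exclude_singletons=False)
        assert np.all(curve.ehh == 1.0)

    def test_fewer_than_two_carriers_rejected(self):
        codes = np.array([[0, 1, 1, 1]])
        haps = make_haps(codes, positions=[10])
        cs = self._core_set(haps, (5, 15))
        # core carried by a single haplotype
        singleton_core = cs.frequencies.index(min(cs.frequencies))
        with pytest.raises(ValueError):
            ehh_decay(haps, cs, singleton_core, "downstream")

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_and_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16)) * 2
        m = int(rng.integers(2, 12))
        codes = rng.integers(0, 2, size=(m + 1, n))
        codes[0] = 0  # shared core site
        haps = make_haps(codes, positions=list(range(10, 10 + (m + 1) * 10, 10)))
        cs = self._core_set(haps, (5, 15))
        curve = ehh_decay(haps, cs, 0, "downstream", exclude_singletons=False)
        assert np.all(np.diff(curve.ehh) <= 1e-12)
        assert np.all(curve.ehh <= 1.0)
        rows = np.arange(1, m + 1)
        oracle = _brute_force_ehh(codes, np.arange(n), rows)
        assert curve.ehh == pytest.approx(oracle)


class TestWindowHomozygosity:
    def test_single_class_is_one(self):
        haps = make_haps(np.zeros((2, 4)), positions=[10, 20])
        out = window_homozygosity(haps, [(5, 25)], np.arange(4))
        assert out.loc[0, "homozygosity"] == 1.0

    def test_all_distinct_is_zero(self):
        codes = np.array([[0, 0, 1, 1], [0, 1, 0, 1]])
        haps = make_haps(codes, positions=[10, 20])
        out = window_homozygosity(haps, [(5, 25)], np.arange(4))
        assert out.loc[0, "homozygosity"] == 0.0

    def test_two_pairs_gives_one_third(self):
        codes = np.array([[0, 0, 1, 1]])
        haps = make_haps(codes, positions=[10])
        out = window_homozygosity(haps, [(5, 25)], np.arange(4))
        assert out.loc[0, "homozygosity"] == pytest.approx(1 / 3)

    def test_empty_windows_rejected(self):
        haps = make_haps(np.zeros((1, 4)))
        with pytest.raises(ValueError):
            window_homozygosity(haps, [], np.arange(4))


class TestDivergenceScan:
    def test_identical_groups_zero_everywhere(self):
        haps = make_haps(np.zeros((3, 8)), positions=[10, 20, 30])
        frame, tracts = divergence_region_scan(
            haps, np.arange(4), np.arange(4, 8), [(1, 50)]
        )
        assert frame["n_fixed"].sum() == 0
        assert tracts == []

    def test_planted_tract_recovered_exactly(self):
        codes = np.zeros((8, 8), dtype=int)
        # sites 2..7 (positions 30..80) fixed differences between the groups
        codes[2:8, 4:] = 1
        haps = make_haps(codes, positions=[10, 20, 30, 40, 50, 60, 70, 80])
        windows = [(1, 25), (25, 65), (65, 95), (95, 120)]
        frame, tracts = divergence_region_scan(
            haps, np.arange(4), np.arange(4, 8), windows
        )
        assert len(tracts) == 1
        assert tracts[0]["n_fixed"] == 6
        assert tracts[0]["start"] == 25 and tracts[0]["end"] == 95

    def test_polymorphic_site_not_counted(self):
        codes = np.zeros((1, 8), dtype=int)
        codes[0, 4:] = 1
        codes[0, 0] = 1  # polymorphic within group A
        haps = make_haps(codes, positions=[10])
        frame, _ = divergence_region_scan(haps, np.arange(4), np.arange(4, 8), [(1, 20)])
        assert frame.loc[0, "n_fixed"] == 0


class TestGeneticMap:
    def test_constant_rate_cumulative(self):
        gmap = GeneticMap.constant(1, 1_000_001, rate=1.0)
        assert gmap.cumulative_cm(1_000_001) == pytest.approx(1.0)
        assert gmap.cm_between(250_001, 750_001) == pytest.approx(0.5)

    def test_piecewise_segments_must_tile(self):
        with pytest.raises(ValueError):
            GeneticMap(segments=[(1, 100, 1.0), (200, 300, 1.0)])


class TestSharedLengths:
    def test_identical_pair_censored_full_span(self):
        codes = np.zeros((4, 4))
        haps = make_haps(codes, positions=[10, 100_000, 900_000, 1_999_990])
        gmap = GeneticMap.constant(1, 2_000_001, rate=1.0)
        res = shared_haplotype_lengths(
            haps, np.array([0, 1]), (999_000, 1_001_000), gmap,
            exclude_singletons=False, bootstrap_reps=10, seed=0,
        )
        assert res.lengths_cm[0] == pytest.approx(2.0)
        assert res.n_censored == 1

    def test_immediate_mismatch_leaves_core_length(self):
        codes = np.array([[0, 1], [0, 0], [0, 1]])
        haps = make_haps(codes, positions=[998_000, 1_000_000, 1_002_000])
        gmap = GeneticMap.constant(1, 2_000_001, rate=1.0)
        res = shared_haplotype_lengths(
            haps, np.array([0, 1]), (999_000, 1_001_000), gmap,
            exclude_singletons=False, bootstrap_reps=10, seed=0,
        )
        # mismatch at the first flanking site on each side: the shared
        # interval is essentially the 2-kb core (0.002 cM at 1 cM/Mb),
        # bounded by the mismatch positions 998,000 and 1,002,000
        assert res.lengths_cm[0] == pytest.approx(0.004, abs=1e-9)

    def test_single_bootstrap_rep_degenerate_ci(self):
        codes = np.zeros((2, 4))
        haps = make_haps(codes, positions=[10, 20])
        gmap = GeneticMap.constant(1, 101, rate=1.0)
        res = shared_haplotype_lengths(
            haps, np.array([0, 1]), (12, 18), gmap,
            exclude_singletons=False, bootstrap_reps=1, seed=0,
        )
        assert res.ci[0] == res.ci[1] == pytest.approx(res.median_cm)


class TestDetectionYearCorrelation:
    def test_collinear(self):
        groups = {"a": (2000, 1.0), "b": (2005, 2.0), "c": (2010, 3.0)}
        r, p, defined = detection_year_correlation(groups)
        assert defined and r == pytest.approx(1.0)

    def test_hand_zero_correlation(self):
        groups = {"a": (0, 0.0), "b": (1, 1.0), "c": (2, 0.0)}
        r, _, defined = detection_year_correlation(groups)
        assert defined and r == pytest.approx(0.0, abs=1e-12)

    def test_anticollinear(self):
        groups = {"a": (2000, 3.0), "b": (2005, 2.0), "c": (2010, 1.0)}
        r, _, defined = detection_year_correlation(groups)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        groups = {"a": (2000, 1.0), "b": (2000, 2.0), "c": (2000, 3.0)}
        _, _, defined = detection_year_correlation(groups)
        assert not defined

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            detection_year_correlation({"a": (1, 1.0), "b": (2, 2.0)})
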