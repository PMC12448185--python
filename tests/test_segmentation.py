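import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_profile
from oracles import simulate_greedy_merge

from cnseg.genome import ReferenceGenome, Region
from cnseg.io import RegionSet
from cnseg.profile import TOTAL, CNProfile
from cnseg.segmentation import (
    Segmentation,
    SegmentationParams,
    bin_region,
    cohort_breakpoints,
    consistent_segmentation,
    merge_breakpoints,
    subtract_exclusions,
)


def _rs(*triples, name="test"):
    return RegionSet(name, [Region(*t) for t in triples])


class TestSubtractExclusions:
    def test_plain_subtraction(self):
        out = subtract_exclusions(_rs(("chr1", 0, 100)), _rs(("chr1", 40, 60)), 0)
        assert [(r.start, r.end) for r in out] == [(0, 40), (60, 100)]

    def test_small_exclusion_dropped(self):
        out = subtract_exclusions(_rs(("chr1", 0, 100)), _rs(("chr1", 40, 45)), 10)
        assert [(r.start, r.end) for r in out] == [(0, 100)]

    def test_small_fragments_dropped(self):
        out = subtract_exclusions(_rs(("chr1", 0, 100)), _rs(("chr1", 5, 95)), 10)
        assert len(out) == 0

    def test_no_exclusions_identity(self):
        out = subtract_exclusions(_rs(("chr1", 0, 100)), _rs(), 0)
        assert [(r.start, r.end) for r in out] == [(0, 100)]

    def test_multiple_regions_and_chromosomes(self):
        regions = _rs(("chr1", 0, 50), ("chr2", 0, 50))
        out = subtract_exclusions(regions, _rs(("chr1", 10, 20)), 0)
        assert [(r.chrom, r.start, r.end) for r in out] == [
            ("chr1", 0, 10),
            ("chr1", 20, 50),
            ("chr2", 0, 50),
        ]


class TestMergeBreakpoints:
    def test_empty(self):
        assert merge_breakpoints([], 5) == []

    def test_hand_example(self):
        assert merge_breakpoints([10, 12, 30], 5) == [11, 30]

    def test_anchor_semantics_chain(self):
        # anchor 0 captures 4 (8 is beyond m); anchor 8 captures 12
        assert merge_breakpoints([0, 4, 8, 12], 5) == [2, 10]

    def test_matches_direct_simulation(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            n = int(rng.integers(0, 40))
            pos = sorted(set(rng.integers(0, 10_000, size=n).tolist()))
            m = int(rng.integers(0, 500))
            assert merge_breakpoints(pos, m) == simulate_greedy_merge(pos, m)

    def test_output_strictly_increasing_and_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pos = sorted(set(rng.integers(0, 100_000, size=200).tolist()))
            m = int(rng.integers(1, 2000))
            out = merge_breakpoints(pos, m)
            assert all(a < b for a, b in zip(out, out[1:]))
            assert len(out) <= len(pos)
            assert all(pos[0] <= p <= pos[-1] for p in out)

    def test_doubling_m_roughly_halves_count(self):
        # dense regime: many breakpoints per merge window, as in real cohorts
        rng = np.random.default_rng(55)
        pos = sorted(set(rng.integers(0, 1_000_000, size=1000).tolist()))
        m1 = 20_000
        n1 = len(merge_breakpoints(pos, m1))
        n2 = len(merge_breakpoints(pos, 2 * m1))
        assert n2 == pytest.approx(n1 / 2, rel=0.2)


class TestBinRegion:
    def test_c_zero_padding(self):
        bins = bin_region(Region("chr1", 0, 20), 5, "c")
        assert [(b.start, b.end) for b in bins] == [(0, 5), (5, 10), (10, 15), (15, 20)]

    def test_c_small_padding_absorbed(self):
        bins = bin_region(Region("chr1", 0, 22), 5, "c")
        assert [b.start for b in bins] + [22] == [0, 6, 11, 17, 22]

    def test_c_large_padding_extra_bin(self):
        bins = bin_region(Region("chr1", 0, 29), 5, "c")
        assert len(bins) == 6
        lengths = [b.length for b in bins]
        assert max(lengths) - min(lengths) <= 1

    def test_a_remainder_merged(self):
        bins = bin_region(Region("chr1", 0, 22), 5, "a")
        assert [(b.start, b.end) for b in bins] == [(0, 5), (5, 10), (10, 15), (15, 22)]

    def test_a_remainder_kept_when_at_least_half(self):
        bins = bin_region(Region("chr1", 0, 23), 5, "a")
        assert [(b.start, b.end) for b in bins] == [
            (0, 5), (5, 10), (10, 15), (15, 20), (20, 23),
        ]

    def test_region_shorter_than_s_single_bin(self):
        for strategy in "abc":
            assert bin_region(Region("chr1", 10, 14), 5, strategy) == [
                Region("chr1", 10, 14)
            ]

    @pytest.mark.parametrize("strategy", ["a", "b", "c"])
    @pytest.mark.parametrize("s", [7, 10, 33])
    def test_bins_tile_region_exactly(self, strategy, s):
        rng = np.random.default_rng(s)
        for _ in range(100):
            start = int(rng.integers(0, 1000))
            length = int(rng.integers(1, 500))
            region = Region("chr1", start, start + length)
            bins = bin_region(region, s, strategy)
            assert bins[0].start == region.start
            assert bins[-1].end == region.end
            for a, b in zip(bins, bins[1:]):
                assert a.end == b.start
            assert sum(b.length for b in bins) == region.length

    @pytest.mark.parametrize("s", [7, 10, 33])
    def test_c_bin_lengths_within_one_base(self, s):
        rng = np.random.default_rng(s + 1)
        for _ in range(100):
            length = int(rng.integers(1, 2000))
            bins = bin_region(Region("chr1", 0, length), s, "c")
            lengths = [b.length for b in bins]
            assert max(lengths) - min(lengths) <= 1

    @pytest.mark.parametrize("s", [6, 10])
    def test_half_boundary_rules(self, s):
        # a/b merge iff remainder < s/2 (strict); c uses <= s/2
        q = 4
        half = s // 2
        exactly_half = bin_region(Region("chr1", 0, q * s + half), s, "a")
        assert len(exactly_half) == q + 1  # remainder == s/2 kept
        below_half = bin_region(Region("chr1", 0, q * s + half - 1), s, "a")
        assert len(below_half) == q  # remainder < s/2 merged
        c_at_half = bin_region(Region("chr1", 0, q * s + half), s, "c")
        assert len(c_at_half) == q  # padding <= s/2 absorbed
        c_above_half = bin_region(Region("chr1", 0, q * s + half + 1), s, "c")
        assert len(c_above_half) == q + 1


class TestConsistentSegmentation:
    def test_all_steps_skipped_returns_chromosomes(self, toy_genome):
        from cnseg.io import load_region_set

        regions = load_region_set("chromosomes", toy_genome)
        seg = consistent_segmentation(regions)
        assert [(r.chrom, r.start, r.end) for r in seg] == [
            (c, 0, l) for c, l in sorted(toy_genome.chromosomes)
        ]

    def test_cohort_breakpoints_merge_and_split(self, autosome_genome):
        def prof(sid, cut):
            df = pd.DataFrame(
                [("chr1", 0, cut, 2.0), ("chr1", cut, 100, 3.0)],
                columns=["chrom", "start", "end", "cn_total"],
            )
            return CNProfile(sid, df, TOTAL, autosome_genome)

        cohort = {"a": prof("a", 10), "b": prof("b", 12)}
        seg = consistent_segmentation(
            _rs(("chr1", 0, 100)),
            params=SegmentationParams(merge_distance=5),
            cohort=cohort,
            use_cohort_breakpoints=True,
        )
        assert [(r.start, r.end) for r in seg] == [(0, 11), (11, 100)]

    def test_empty_cohort_with_breakpoints_errors(self):
        with pytest.raises(ValueError, match="non-empty cohort"):
            consistent_segmentation(
                _rs(("chr1", 0, 100)), cohort={}, use_cohort_breakpoints=True
            )

    def test_exclusion_then_binning(self):
        # region minus centromere gap -> two arms -> ~s bins per arm (strategy c)
        regions = _rs(("chr1", 0, 100))
        exclusions = _rs(("chr1", 45, 55))
        seg = consistent_segmentation(
            regions,
            exclusions=exclusions,
            params=SegmentationParams(split_size=10, strategy="c"),
        )
        assert all(r.end <= 45 or r.start >= 55 for r in seg)
        left = [r for r in seg if r.end <= 45]
        assert sum(r.length for r in left) == 45
        lengths = [r.length for r in left]
        assert max(lengths) - min(lengths) <= 1

    def test_breakpoints_inside_exclusions_are_dropped(self, autosome_genome):
        df = pd.DataFrame(
            [("chr1", 0, 50, 2.0), ("chr1", 50, 100, 3.0)],
            columns=["chrom", "start", "end", "cn_total"],
        )
        cohort = {"a": CNProfile("a", df, TOTAL, autosome_genome)}
        seg = consistent_segmentation(
            _rs(("chr1", 0, 100)),
            exclusions=_rs(("chr1", 40, 60)),
            cohort=cohort,
            use_cohort_breakpoints=True,
        )
        assert [(r.start, r.end) for r in seg] == [(0, 40), (60, 100)]

    def test_determinism(self, toy_genome):
        rng1 = np.random.default_rng(77)
        rng2 = np.random.default_rng(77)
        cohorts = []
        for rng in (rng1, rng2):
            cohorts.append(
                {f"s{i}": random_profile(toy_genome, rng, f"s{i}") for i in range(4)}
            )
        segs = [
            consistent_segmentation(
                _rs(*[(c, 0, l) for c, l in toy_genome.chromosomes]),
                params=SegmentationParams(merge_distance=10, split_size=50, strategy="b"),
                cohort=c,
                use_cohort_breakpoints=True,
            )
            for c in cohorts
        ]
        assert [(r.chrom, r.start, r.end) for r in segs[0]] == [
            (r.chrom, r.start, r.end) for r in segs[1]
        ]

    def test_segmentation_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            Segmentation([Region("chr1", 0, 10), Region("chr1", 5, 20)])

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(filter_size=-1)
        with pytest.raises(ValueError):
            SegmentationParams(strategy="z")


def test_cohort_breakpoints_excludes_chromosome_edges(autosome_genome):
    df = pd.DataFrame(
        [("chr1", 0, 40, 2.0), ("chr1", 60, 100, 3.0)],
        columns=["chrom", "start", "end", "cn_total"],
    )
    cohort = {"a": CNProfile("a", df, TOTAL, autosome_genome)}
    assert cohort_breakpoints(cohort) == {"chr1": [40, 60]}
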