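import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domestiscan.io_formats import GeneModel, GenomicInterval
from domestiscan.sweep_scan import (
    empirical_threshold,
    genes_in_regions,
    merge_windows,
    select_sweep_windows,
)


def frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "rod"])


class TestEmpiricalThreshold:
    def test_nearest_rank_on_1_to_100(self):
        values = np.arange(1.0, 101.0)
        thr = empirical_threshold(values, 0.05)
        assert thr == 95.0
        assert sorted(values[values > thr]) == [96, 97, 98, 99, 100]

    def test_all_equal_values_select_nothing(self):
        values = np.full(50, 3.3)
        thr = empirical_threshold(values)
        assert thr == 3.3
        assert (values > thr).sum() == 0

    def test_twenty_values_use_19th_order_statistic(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=20)
        assert empirical_threshold(values) == np.sort(values)[18]

    def test_nan_values_excluded(self):
        values = np.concatenate([np.arange(1.0, 101.0), [np.nan] * 30])
        assert empirical_threshold(values, 0.05) == 95.0

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            empirical_threshold(np.array([np.nan] * 25))

    def test_selected_fraction_never_exceeds_tail(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            values = rng.normal(size=rng.integers(20, 500))
            thr = empirical_threshold(values, 0.05)
            assert (values > thr).sum() <= 0.05 * len(values)


class TestSelectSweepWindows:
    def test_window_exceeding_both_thresholds_selected(self):
        stats = frame([("chr1", 0, 100_000, 0.05, 0.60)])
        sel = select_sweep_windows(stats, 0.041, 0.569)
        assert len(sel) == 1

    def test_undefined_statistic_excludes_window(self):
        stats = frame([("chr1", 0, 100_000, 0.05, np.nan)])
        assert len(select_sweep_windows(stats, 0.041, 0.569)) == 0

    def test_no_window_passing_both_gives_empty(self):
        stats = frame(
            [("chr1", 0, 100_000, 0.05, 0.1), ("chr1", 10_000, 110_000, 0.01, 0.9)]
        )
        assert len(select_sweep_windows(stats, 0.041, 0.569)) == 0

    def test_selection_is_strict(self):
        stats = frame([("chr1", 0, 100_000, 0.041, 0.60)])
        assert len(select_sweep_windows(stats, 0.041, 0.569)) == 0


class TestMergeWindows:
    def test_overlapping_windows_merge(self):
        regions = merge_windows(
            frame(
                [
                    ("chr1", 0, 100_000, 0.1, 0.7),
                    ("chr1", 10_000, 110_000, 0.2, 0.6),
                ]
            )
        )
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (0, 110_000)
        assert regions[0].n_windows == 2
        assert regions[0].max_fst == 0.2
        assert regions[0].max_rod == 0.7

    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows(
            frame(
                [
                    ("chr1", 0, 100_000, 0.1, 0.7),
                    ("chr1", 200_000, 300_000, 0.2, 0.6),
                ]
            )
        )
        assert len(regions) == 2

    def test_book_ended_windows_merge(self):
        regions = merge_windows(
            frame(
                [
                    ("chr1", 0, 100_000, 0.1, 0.7),
                    ("chr1", 100_000, 200_000, 0.2, 0.6),
                ]
            )
        )
        assert len(regions) == 1
        assert regions[0].interval.end == 200_000

    def test_different_chromosomes_never_merge(self):
        regions = merge_windows(
            frame(
                [
                    ("chr1", 0, 100_000, 0.1, 0.7),
                    ("chr2", 0, 100_000, 0.2, 0.6),
                ]
            )
        )
        assert len(regions) == 2

    def test_empty_selection_gives_no_regions(self):
        assert merge_windows(frame([])) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_merge_is_idempotent(self, windows):
        df = frame(
            [(c, s * 10_000, s * 10_000 + 100_000, 0.1, 0.5) for c, s in windows]
        )
        once = merge_windows(df)
        again = merge_windows(
            frame(
                [
                    (r.interval.chrom, r.interval.start, r.interval.end, r.max_fst, r.max_rod)
                    for r in once
                ]
            )
        )
        assert [r.interval for r in once] == [r.interval for r in again]
        # non-overlapping, sorted output
        for a, b in zip(once, once[1:]):
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start


class TestGenesInRegions:
    def region(self, chrom, start, end):
        return merge_windows(frame([(chrom, start, end, 0.1, 0.7)]))

    def test_contained_gene_attached(self):
        regions = self.region("chr1", 140_000, 170_000)
        gene = GeneModel("g1", "chr1", 150_001, 160_000)
        regions, flat = genes_in_regions(regions, [gene])
        assert regions[0].genes == ["g1"]
        assert flat == ["g1"]

    def test_gene_ending_at_region_start_not_attached(self):
        # gene footprint [start-1, end) ends exactly where the region begins
        regions = self.region("chr1", 140_000, 170_000)
        gene = GeneModel("g1", "chr1", 139_000, 140_000)
        _, flat = genes_in_regions(regions, [gene])
        assert flat == []

    def test_one_bp_overlap_attaches(self):
        regions = self.region("chr1", 140_000, 170_000)
        gene = GeneModel("g1", "chr1", 139_000, 140_001)
        _, flat = genes_in_regions(regions, [gene])
        assert flat == ["g1"]

    def test_gene_spanning_two_regions_counted_once(self):
        df = frame(
            [
                ("chr1", 0, 100_000, 0.1, 0.7),
                ("chr1", 200_000, 300_000, 0.1, 0.7),
            ]
        )
        regions = merge_windows(df)
        gene = GeneModel("g1", "chr1", 90_001, 210_000)
        regions, flat = genes_in_regions(regions, [gene])
        assert regions[0].genes == ["g1"] and regions[1].genes == ["g1"]
        assert flat == ["g1"]
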