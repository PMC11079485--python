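import numpy as np
import pytest

from _oracles import brute_pi_window, brute_weighted_fst, wc_components_scalar
from conftest import make_matrix, random_matrix
from domestiscan.io_formats import GenomicInterval
from domestiscan.popgen_windows import (
    WindowSpec,
    compute_window_stats,
    make_windows,
    rod,
    site_fst_components,
    site_pi,
    windowed_fst,
    windowed_pi,
)


class TestMakeWindows:
    def test_full_chromosome_tiling(self):
        w = make_windows({"chr1": 250_000}, WindowSpec(100_000, 10_000))
        assert len(w) == 25
        assert (w[0].start, w[0].end) == (0, 100_000)
        assert (w[-1].start, w[-1].end) == (240_000, 250_000)

    def test_chromosome_shorter_than_window(self):
        w = make_windows({"chr1": 50_000}, WindowSpec(100_000, 10_000))
        assert len(w) == 5
        assert (w[0].start, w[0].end) == (0, 50_000)

    def test_degenerate_single_window(self):
        w = make_windows({"chr1": 1000}, WindowSpec(1000, 1000))
        assert w == [GenomicInterval("chr1", 0, 1000)]

    def test_every_bp_covered(self):
        length = 123_456
        w = make_windows({"chr1": length}, WindowSpec(10_000, 3_000))
        covered = np.zeros(length, dtype=bool)
        for iv in w:
            covered[iv.start : iv.end] = True
        assert covered.all()

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"chr1": 0})


class TestSitePi:
    def test_balanced_counts(self):
        # 4 alleles, C(4,2)=6 pairs of which 2x2=4 differ
        assert site_pi(2, 2) == pytest.approx(4 / 6)

    def test_monomorphic_site_is_zero(self):
        assert site_pi(5, 0) == 0.0

    def test_two_distinct_alleles(self):
        assert site_pi(1, 1) == 1.0

    def test_fewer_than_two_alleles_undefined(self):
        assert np.isnan(site_pi(1, 0))

    def test_brute_force_pair_enumeration(self):
        import itertools

        for r, a in [(3, 5), (7, 1), (4, 4), (10, 2)]:
            alleles = [0] * r + [1] * a
            pairs = list(itertools.combinations(alleles, 2))
            expected = sum(x != y for x, y in pairs) / len(pairs)
            assert site_pi(r, a) == pytest.approx(expected, abs=1e-15)


class TestWindowedPi:
    def test_single_snp_full_window(self):
        gm = make_matrix([[1, 1, 0, 0]], positions=[5000])
        w = [GenomicInterval("chr1", 0, 100_000)]
        pi = windowed_pi(gm, gm.sample_ids, w)
        # dosages (1,1,0,0): 2 ALT / 6 REF alleles -> site pi = 2*6/C(8,2);
        # denominator is the window length
        assert pi[0] == pytest.approx((12 / 28) / 100_000)

    def test_empty_window_is_zero(self):
        gm = make_matrix([[1, 1, 0, 0]], positions=[5000])
        assert windowed_pi(gm, gm.sample_ids, [GenomicInterval("chr1", 50_000, 100_000)])[0] == 0.0

    def test_truncated_window_uses_truncated_length(self):
        gm = make_matrix([[1, 1, 0, 0]], positions=[5000])
        full = windowed_pi(gm, gm.sample_ids, [GenomicInterval("chr1", 0, 100_000)])[0]
        trunc = windowed_pi(gm, gm.sample_ids, [GenomicInterval("chr1", 0, 50_000)])[0]
        assert trunc == pytest.approx(2 * full)

    def test_empty_population_rejected(self):
        gm = make_matrix([[1, 1, 0, 0]])
        with pytest.raises(ValueError):
            windowed_pi(gm, [], [GenomicInterval("chr1", 0, 1000)])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_matrix(rng, n_sites=40, n_samples=15, missing_rate=0.15)
        pop = gm.sample_ids[:8]
        cols = list(range(8))
        windows = [
            GenomicInterval("chr1", 0, 20_000),
            GenomicInterval("chr1", 15_000, 35_000),
            GenomicInterval("chr1", 30_000, 50_000),
        ]
        got = windowed_pi(gm, pop, windows)
        for iv, val in zip(windows, got):
            expected = brute_pi_window(
                gm.dosage.tolist(), gm.pos.tolist(), cols, iv.start, iv.end
            )
            assert val == pytest.approx(expected, abs=1e-12)


class TestSiteFst:
    def test_fixed_difference_gives_one(self):
        a, b, c = site_fst_components((10, 0, 0), (0, 0, 10))
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_populations_non_positive(self):
        a, b, c = site_fst_components((3, 4, 3), (3, 4, 3))
        assert a + b + c > 0
        assert a / (a + b + c) <= 0

    def test_hand_fixture_matches_scalar_oracle(self):
        got = site_fst_components((3, 2, 0), (0, 2, 3))
        expected = wc_components_scalar((3, 2, 0), (0, 2, 3))
        assert got == pytest.approx(expected, abs=1e-14)


class TestWindowedFst:
    def test_fixed_difference_window_is_one(self):
        dosage = [[0, 0, 0, 2, 2, 2]] * 5
        gm = make_matrix(dosage)
        fst = windowed_fst(
            gm, gm.sample_ids[:3], gm.sample_ids[3:], [GenomicInterval("chr1", 0, 1000)]
        )
        assert fst[0] == pytest.approx(1.0)

    def test_window_without_snps_undefined(self):
        gm = make_matrix([[0, 1, 2, 1]], positions=[10])
        fst = windowed_fst(
            gm, gm.sample_ids[:2], gm.sample_ids[2:], [GenomicInterval("chr1", 5000, 6000)]
        )
        assert np.isnan(fst[0])

    def test_overlapping_populations_rejected(self):
        gm = make_matrix([[0, 1, 2, 1]])
        with pytest.raises(ValueError):
            windowed_fst(gm, gm.sample_ids[:3], gm.sample_ids[2:], [])

    @pytest.mark.parametrize("seed", range(4))
    def test_ratio_of_sums_matches_site_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        gm = random_matrix(rng, n_sites=10, n_samples=16, missing_rate=0.1, span=900)
        cols1, cols2 = list(range(8)), list(range(8, 16))
        w = GenomicInterval("chr1", 0, 1000)
        got = windowed_fst(gm, gm.sample_ids[:8], gm.sample_ids[8:], [w])[0]
        expected = brute_weighted_fst(
            gm.dosage.tolist(), gm.pos.tolist(), cols1, cols2, w.start, w.end
        )
        assert got == pytest.approx(expected, abs=1e-12, nan_ok=True)


class TestRod:
    def test_direct_formula(self):
        assert rod(0.001, 0.004) == pytest.approx(0.75)

    def test_equal_diversity_is_zero(self):
        assert rod(0.0123, 0.0123) == pytest.approx(0.0)

    def test_diversity_gain_is_negative(self):
        assert rod(0.006, 0.004) == pytest.approx(-0.5)

    def test_zero_wild_pi_undefined(self):
        assert np.isnan(rod(0.001, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rod(-0.1, 0.2)

    def test_strictly_decreasing_in_pop1_and_one_iff_zero(self):
        pi2 = 0.004
        values = [rod(p1, pi2) for p1 in np.linspace(0.0, 0.01, 25)]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[0] == 1.0
        assert all(v < 1.0 for v in values[1:])


def test_window_stats_invariant_to_sample_and_chromosome_order():
    rng = np.random.default_rng(42)
    n_sites, n_samples = 30, 12
    dosage = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    chrom = np.array(["chr1"] * 15 + ["chr2"] * 15, dtype=object)
    pos = np.concatenate([np.sort(rng.choice(9000, 15, replace=False)) + 1] * 2)
    gm = make_matrix(dosage, positions=pos, chrom=chrom)
    pop1, pop2 = gm.sample_ids[:6], gm.sample_ids[6:]
    windows = [GenomicInterval("chr1", 0, 10_000), GenomicInterval("chr2", 0, 10_000)]

    base = compute_window_stats(gm, pop1, pop2, windows)

    shuffled_pop1 = list(reversed(pop1))
    perm = rng.permutation(n_sites)
    order = np.lexsort((gm.pos[perm], gm.chrom[perm].astype(str)))
    gm2 = gm.take_sites(perm[order])
    again = compute_window_stats(gm2, shuffled_pop1, pop2, list(reversed(windows)))

    for col in ("pi_pop1", "pi_pop2", "fst", "rod"):
        np.testing.assert_allclose(
            base.sort_values(["chrom", "start"])[col].to_numpy(),
            again.sort_values(["chrom", "start"])[col].to_numpy(),
            atol=1e-14,
        )
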