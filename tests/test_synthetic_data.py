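import numpy as np
import pandas as pd
import pytest

from domestiscan import synthetic_data as sd
from domestiscan.allele_evolution import classify_dea, ng86_ka_ks
from domestiscan.io_formats import MISSING, read_gff3, read_population_map, read_vcf

SMALL = sd.SimParams(
    n_chrom=1,
    chrom_length=200_000,
    sweep_intervals=(),
    n_wild=6,
    n_cult=6,
)


class TestTwoPopCohort:
    def test_fixed_seed_reproduces_byte_identical_vcf(self, tmp_path):
        p1, _, _ = sd.simulate_two_pop_vcf(SMALL, seed=9, out_dir=tmp_path / "a")
        p2, _, _ = sd.simulate_two_pop_vcf(SMALL, seed=9, out_dir=tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_changes_output(self, tmp_path):
        p1, _, _ = sd.simulate_two_pop_vcf(SMALL, seed=9, out_dir=tmp_path / "a")
        p2, _, _ = sd.simulate_two_pop_vcf(SMALL, seed=10, out_dir=tmp_path / "b")
        assert p1.read_bytes() != p2.read_bytes()

    def test_output_parses_cleanly_with_readers(self, tmp_path):
        vcf, popmap, _ = sd.simulate_two_pop_vcf(SMALL, seed=2, out_dir=tmp_path)
        gm, skipped = read_vcf(vcf, keep_info=True)
        assert skipped == 0
        assert gm.n_sites > 0
        assert gm.contig_lengths == {"chr1": 200_000}
        assert set(gm.site_annotations) == {
            "QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum"
        }
        pm = read_population_map(popmap)
        assert pm.sizes() == {"wild": 6, "cultivated": 6}

    def test_no_divergence_limit(self):
        params = sd.SimParams(
            n_chrom=1, chrom_length=300_000, sweep_intervals=(),
            fst=0.0, missing_rate=0.0, n_wild=120, n_cult=120,
        )
        gm, pm, _ = sd.simulate_two_pop_genotypes(params, seed=0)
        wild = gm.sample_indices(pm.samples("wild"))
        cult = gm.sample_indices(pm.samples("cultivated"))
        dp = np.abs(
            gm.dosage[:, wild].mean(axis=1) - gm.dosage[:, cult].mean(axis=1)
        ) / 2.0
        # pure binomial sampling noise: E|dp| ~ sqrt(2 p q / 2n) ~< 0.04
        assert dp.mean() < 0.06

    def test_sweep_sites_lose_cultivated_diversity(self):
        params = sd.SimParams(
            n_chrom=1,
            chrom_length=1_000_000,
            sweep_intervals=(sd.GenomicInterval("chr1", 200_000, 600_000),),
            sweep_intensity=1.0,
            missing_rate=0.0,
        )
        gm, pm, truth = sd.simulate_two_pop_genotypes(params, seed=1)
        cult = gm.sample_indices(pm.samples("cultivated"))
        in_sweep = (gm.pos - 1 >= 200_000) & (gm.pos - 1 < 600_000)
        cult_freq = gm.dosage[:, cult].mean(axis=1) / 2.0
        mono = (cult_freq == 0.0) | (cult_freq == 1.0)
        assert mono[in_sweep].all()
        assert not mono[~in_sweep].all()

    def test_sweep_interval_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sd.SimParams(
                n_chrom=1,
                chrom_length=100_000,
                sweep_intervals=(sd.GenomicInterval("chr1", 50_000, 200_000),),
            )

    def test_planted_info_failures_fraction(self):
        params = sd.SimParams(
            n_chrom=1, chrom_length=500_000, sweep_intervals=(),
            info_fail_fraction=0.1,
        )
        gm, _, _ = sd.simulate_two_pop_genotypes(params, seed=5)
        from domestiscan.variant_filtering import apply_hard_filters

        out, per_rule = apply_hard_filters(gm)
        removed = gm.n_sites - out.n_sites
        assert removed == pytest.approx(0.1 * gm.n_sites, rel=0.15)


class TestGff:
    def test_genes_valid_and_non_overlapping(self, tmp_path):
        path = tmp_path / "g.gff3"
        genes = sd.simulate_gff({"chr1": 1_000_000}, 10, seed=0, out_path=path)
        assert len(genes) == 10
        assert read_gff3(path) == sorted(genes, key=lambda g: (g.chrom, g.start))
        by_chrom = sorted((g.start, g.end) for g in genes)
        for (s1, e1), (s2, e2) in zip(by_chrom, by_chrom[1:]):
            assert e1 < s2

    def test_genes_forced_into_sweeps(self):
        params = sd.SimParams()
        truth = sd.SimulationTruth(params, 0, params.sweep_intervals)
        genes = sd.simulate_gff(
            params.chrom_lengths(), 30, seed=1, truth=truth, genes_per_sweep=2
        )
        for sweep in truth.sweep_intervals:
            inside = [
                g for g in genes if g.interval().overlaps(sweep)
                and g.interval().start >= sweep.start
                and g.interval().end <= sweep.end
            ]
            assert len(inside) >= 2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_gff({"chr1": 10_000}, 100, seed=0, gene_length=3000)


class TestCdsPairs:
    def test_near_zero_dnds_suppresses_ka(self):
        pairs = sd.simulate_cds_pairs(5, 400, dnds=1e-6, seed=3)
        for _, a, b in pairs:
            ka, ks, _ = ng86_ka_ks(a, b)
            assert ka < 0.005
            assert ks > 0.0

    def test_zero_divergence_gives_identical_pairs(self):
        pairs = sd.simulate_cds_pairs(3, 100, dnds=0.5, divergence=0.0, seed=0)
        for _, a, b in pairs:
            assert a == b
            ka, ks, _ = ng86_ka_ks(a, b)
            assert ka == 0.0 and ks == 0.0

    def test_no_internal_stops_introduced(self):
        from domestiscan.allele_evolution import STOP_CODONS

        pairs = sd.simulate_cds_pairs(5, 300, dnds=2.0, divergence=0.3, seed=6)
        for _, a, b in pairs:
            for seq in (a, b):
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & STOP_CODONS)

    def test_fasta_writer_round_trip(self, tmp_path):
        from Bio import SeqIO

        pairs = sd.simulate_cds_pairs(4, 60, dnds=0.5, seed=2)
        sd.write_cds_pair_fastas(
            pairs, tmp_path / "a.fa", tmp_path / "b.fa", tmp_path / "pairs.tsv"
        )
        a = {r.id: str(r.seq) for r in SeqIO.parse(str(tmp_path / "a.fa"), "fasta")}
        assert a["pair0001|a"] == pairs[0][1]
        assert len(a) == 4


class TestExpressionPairs:
    def test_noiseless_labels_recovered_exactly(self):
        table, truth = sd.simulate_expression_pairs(
            200, frac_dea=0.4, lfc_magnitude=2.0, noise_sd=0.0, seed=8
        )
        called = classify_dea(table).set_index("pair_id")["label"]
        assert (called.sort_index() == truth.sort_index()).all()

    def test_zero_dea_fraction(self):
        table, truth = sd.simulate_expression_pairs(
            100, frac_dea=0.0, noise_sd=0.0, seed=1
        )
        assert (truth == "EEA").all()
        assert (classify_dea(table)["label"] == "EEA").all()

    def test_deterministic_given_seed(self):
        t1, _ = sd.simulate_expression_pairs(50, seed=13)
        t2, _ = sd.simulate_expression_pairs(50, seed=13)
        pd.testing.assert_frame_equal(t1, t2)


def test_telomeric_fasta_deterministic_and_bounded(tmp_path):
    p1 = tmp_path / "a.fa"
    p2 = tmp_path / "b.fa"
    sd.simulate_telomeric_fasta({"chr1": 50_000}, repeats_per_end=20, seed=3, out_path=p1)
    sd.simulate_telomeric_fasta({"chr1": 50_000}, repeats_per_end=20, seed=3, out_path=p2)
    assert p1.read_bytes() == p2.read_bytes()
    with pytest.raises(ValueError):
        sd.simulate_telomeric_fasta({"chr1": 1000}, repeats_per_end=100)
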