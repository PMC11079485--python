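import textwrap

import numpy as np
import pytest

from domestiscan.io_formats import MISSING, GenotypeMatrix

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##contig=<ID=chr2,length=500000>
    ##INFO=<ID=QD,Number=1,Type=Float,Description="x">
    ##INFO=<ID=MQ,Number=1,Type=Float,Description="x">
    ##INFO=<ID=FS,Number=1,Type=Float,Description="x">
    ##INFO=<ID=SOR,Number=1,Type=Float,Description="x">
    ##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="x">
    ##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    """
)


@pytest.fixture
def write_vcf(tmp_path):
    """Write a small VCF from body lines; returns the path."""

    def _write(body_lines, samples=("s1", "s2", "s3"), name="test.vcf"):
        path = tmp_path / name
        header = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        header += "\t".join(samples) + "\n"
        path.write_text(header + "".join(line + "\n" for line in body_lines))
        return path

    return _write


def make_matrix(dosage, positions=None, chrom="chr1", annotations=None,
                contig_lengths=None):
    """GenotypeMatrix from a plain dosage list-of-lists."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    chrom_arr = (
        np.array(chrom, dtype=object)
        if not isinstance(chrom, str)
        else np.array([chrom] * n_sites, dtype=object)
    )
    return GenotypeMatrix(
        chrom=chrom_arr,
        pos=np.asarray(positions, dtype=np.int64),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["G"] * n_sites, dtype=object),
        dosage=dosage,
        sample_ids=[f"s{i}" for i in range(n_samples)],
        site_annotations=annotations,
        contig_lengths=contig_lengths,
    )


def random_matrix(rng, n_sites=30, n_samples=10, missing_rate=0.1, span=50_000):
    """Random matrix with missingness for oracle-equivalence checks."""
    dosage = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    mask = rng.uniform(size=dosage.shape) < missing_rate
    dosage[mask] = MISSING
    positions = np.sort(rng.choice(span, size=n_sites, replace=False)) + 1
    return make_matrix(dosage, positions=positions)
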