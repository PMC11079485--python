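"""Synthetic inputs with the statistical structure the scan assumes.

Every generator is a pure function of its parameters and a seed, so all
pipeline stages are testable without any external download:

* a two-population (wild / cultivated) diploid SNP cohort whose allele
  frequencies follow the Balding-Nichols model — both populations draw
  beta-distributed frequencies around a shared ancestral frequency with
  divergence parameter F, which makes F the expected genome-wide
  Weir-Cockerham F_ST — with planted sweep intervals where cultivated
  frequencies are pushed to fixation (low cultivated pi, high ROD and
  F_ST);
* gene models (GFF3), optionally forced into the planted sweeps;
* CDS pairs evolved under a chosen dN/dS;
* allele-pair expression tables with a chosen DEA fraction;
* chromosome FASTA with exact telomeric repeat arrays planted at the ends;
* genotypes with distance-decaying LD from a haplotype copying model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenomicInterval, GenotypeMatrix, PopulationMap

__all__ = [
    "SimParams",
    "SimulationTruth",
    "simulate_two_pop_genotypes",
    "simulate_two_pop_vcf",
    "simulate_gff",
    "simulate_cds_pairs",
    "simulate_expression_pairs",
    "simulate_telomeric_fasta",
    "simulate_ld_genotypes",
]

_DEFAULT_SWEEPS = (
    GenomicInterval("chr1", 1_000_000, 1_300_000),
    GenomicInterval("chr1", 3_000_000, 3_300_000),
    GenomicInterval("chr2", 500_000, 800_000),
    GenomicInterval("chr2", 2_200_000, 2_500_000),
    GenomicInterval("chr2", 4_000_000, 4_300_000),
)


@dataclass(frozen=True)
class SimParams:
    """Generating parameters of the two-population cohort.

    Defaults describe a desk-scale study: a 10-Mb genome on two
    chromosomes, one SNP per kb, 40 diploids per population, background
    divergence F = 0.05, five planted 300-kb sweeps, 2% missing genotypes
    and 2% of sites planted to fail the hard filters.
    """

    n_chrom: int = 2
    chrom_length: int = 5_000_000
    snp_density: float = 0.001  # expected SNPs per bp
    n_wild: int = 40
    n_cult: int = 40
    fst: float = 0.05
    sweep_intervals: tuple[GenomicInterval, ...] = _DEFAULT_SWEEPS
    sweep_intensity: float = 0.9  # per-site fixation probability inside sweeps
    missing_rate: float = 0.02
    info_fail_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_wild < 4 or self.n_cult < 4:
            raise ValueError("need >= 4 diploids per population")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("F must be in [0, 1)")
        chroms = self.chrom_names()
        for iv in self.sweep_intervals:
            if iv.chrom not in chroms or iv.end > self.chrom_length:
                raise ValueError(f"sweep interval {iv} outside chromosomes")
        for a, b in zip(self.sweep_intervals, self.sweep_intervals[1:]):
            if a.overlaps(b):
                raise ValueError("sweep intervals overlap")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


@dataclass(frozen=True)
class SimulationTruth:
    """Planted structure of one simulated cohort."""

    params: SimParams
    seed: int
    sweep_intervals: tuple[GenomicInterval, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "params": {
                k: v
                for k, v in asdict(self.params).items()
                if k != "sweep_intervals"
            },
            "sweep_intervals": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                for iv in self.sweep_intervals
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 -> p."""
    if f == 0.0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_two_pop_genotypes(
    params: SimParams = SimParams(), seed: int = 0
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """In-memory two-population cohort with planted sweeps.

    Per site: ancestral frequency ``p ~ U(0.05, 0.95)``; wild and
    cultivated ALT frequencies each ~ Balding-Nichols(p, F); inside a
    sweep interval the cultivated frequency is pushed to the nearer
    fixation state with probability ``sweep_intensity``.  Genotypes are
    ``Binomial(2, freq)`` per diploid, masked missing at ``missing_rate``.
    INFO annotations are drawn from comfortably passing distributions,
    except a planted ``info_fail_fraction`` of sites that violate one
    randomly chosen hard-filter rule.
    """
    rng = np.random.default_rng(seed)
    chroms: list[str] = []
    poss: list[int] = []
    for c in params.chrom_names():
        n_sites = rng.poisson(params.snp_density * params.chrom_length)
        pos = np.sort(
            rng.choice(params.chrom_length, size=n_sites, replace=False)
        ) + 1  # 1-based
        chroms.extend([c] * n_sites)
        poss.extend(pos.tolist())
    chrom_arr = np.array(chroms, dtype=object)
    pos_arr = np.array(poss, dtype=np.int64)
    n_sites = len(pos_arr)

    p = rng.uniform(0.05, 0.95, size=n_sites)
    f_wild = _balding_nichols(rng, p, params.fst)
    f_cult = _balding_nichols(rng, p, params.fst)
    in_sweep = np.zeros(n_sites, dtype=bool)
    for iv in params.sweep_intervals:
        in_sweep |= (chrom_arr == iv.chrom) & (pos_arr - 1 >= iv.start) & (
            pos_arr - 1 < iv.end
        )
    fixed = in_sweep & (rng.uniform(size=n_sites) < params.sweep_intensity)
    f_cult = np.where(fixed, np.round(f_cult), f_cult)

    n_total = params.n_wild + params.n_cult
    dosage = np.empty((n_sites, n_total), dtype=np.int8)
    dosage[:, : params.n_wild] = rng.binomial(
        2, f_wild[:, None], size=(n_sites, params.n_wild)
    )
    dosage[:, params.n_wild :] = rng.binomial(
        2, f_cult[:, None], size=(n_sites, params.n_cult)
    )
    if params.missing_rate > 0:
        mask = rng.uniform(size=dosage.shape) < params.missing_rate
        dosage[mask] = MISSING

    annotations = _simulate_info(rng, n_sites, params.info_fail_fraction)
    ref, alt = _simulate_alleles(rng, n_sites)

    sample_ids = [f"wild_{i:03d}" for i in range(params.n_wild)] + [
        f"cult_{i:03d}" for i in range(params.n_cult)
    ]
    gm = GenotypeMatrix(
        chrom=chrom_arr,
        pos=pos_arr,
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
        sample_ids=sample_ids,
        site_annotations=annotations,
        contig_lengths=params.chrom_lengths(),
    )
    popmap = PopulationMap(
        assignments={
            s: ("wild" if s.startswith("wild") else "cultivated")
            for s in sample_ids
        }
    )
    truth = SimulationTruth(
        params=params, seed=seed, sweep_intervals=params.sweep_intervals
    )
    return gm, popmap, truth


def _simulate_alleles(
    rng: np.random.Generator, n_sites: int
) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"), dtype=object)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return bases[ref_idx], bases[alt_idx]


_INFO_PASSING = {
    "QD": (15.0, 35.0),
    "MQ": (55.0, 60.0),
    "FS": (0.0, 10.0),
    "SOR": (0.5, 2.5),
    "MQRankSum": (-2.0, 2.0),
    "ReadPosRankSum": (-2.0, 2.0),
}
_INFO_FAILING = {
    "QD": (0.0, 1.9),
    "MQ": (20.0, 39.0),
    "FS": (61.0, 120.0),
    "SOR": (3.1, 6.0),
    "MQRankSum": (-20.0, -13.0),
    "ReadPosRankSum": (-15.0, -8.5),
}


def _simulate_info(
    rng: np.random.Generator, n_sites: int, fail_fraction: float
) -> dict[str, np.ndarray]:
    ann = {
        k: rng.uniform(lo, hi, size=n_sites)
        for k, (lo, hi) in _INFO_PASSING.items()
    }
    if fail_fraction > 0 and n_sites > 0:
        n_fail = int(round(fail_fraction * n_sites))
        fail_sites = rng.choice(n_sites, size=n_fail, replace=False)
        keys = list(_INFO_FAILING)
        which = rng.integers(0, len(keys), size=n_fail)
        for site, ki in zip(fail_sites, which):
            lo, hi = _INFO_FAILING[keys[ki]]
            ann[keys[ki]][site] = rng.uniform(lo, hi)
    return ann


def simulate_two_pop_vcf(
    params: SimParams = SimParams(),
    seed: int = 0,
    out_dir: str | Path = ".",
) -> tuple[Path, Path, SimulationTruth]:
    """Write the cohort as ``cohort.vcf`` + ``popmap.tsv`` + ``truth.json``.

    Byte-identical output for a fixed (params, seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm, popmap, truth = simulate_two_pop_genotypes(params, seed)
    vcf_path = out_dir / "cohort.vcf"
    _write_vcf(gm, vcf_path)
    popmap_path = out_dir / "popmap.tsv"
    with open(popmap_path, "w") as fh:
        for s, label in popmap.assignments.items():
            fh.write(f"{s}\t{label}\n")
    truth.to_json(out_dir / "truth.json")
    return vcf_path, popmap_path, truth


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan-simulator\n")
        if gm.contig_lengths:
            for c, n in gm.contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={n}>\n")
        keys = list(gm.site_annotations) if gm.site_annotations else []
        for k in keys:
            fh.write(
                f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">\n'
            )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for i in range(gm.n_sites):
            info = (
                ";".join(
                    f"{k}={gm.site_annotations[k][i]:.4f}" for k in keys
                )
                if keys
                else "."
            )
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosage[i])
            fh.write(
                f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref_allele[i]}\t"
                f"{gm.alt_allele[i]}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


def simulate_gff(
    chrom_lengths: Mapping[str, int],
    n_genes: int,
    seed: int = 0,
    truth: SimulationTruth | None = None,
    genes_per_sweep: int = 1,
    gene_length: int = 3_000,
    out_path: str | Path | None = None,
) -> list:
    """Non-overlapping gene models placed uniformly; with ``truth`` given,
    ``genes_per_sweep`` genes are forced inside each planted sweep.

    Returns the gene list (GFF3 written when ``out_path`` set); raises if
    the requested genes cannot be packed.
    """
    from .io_formats import GeneModel

    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}

    def _try_place(chrom: str, lo: int, hi: int) -> tuple[int, int] | None:
        # 0-based half-open candidate within [lo, hi)
        if hi - lo < gene_length:
            return None
        for _ in range(200):
            start = int(rng.integers(lo, hi - gene_length + 1))
            iv = (start, start + gene_length)
            if all(
                iv[1] <= s or iv[0] >= e for s, e in placed[chrom]
            ):
                placed[chrom].append(iv)
                return iv
        return None

    genes: list[GeneModel] = []
    gid = 0

    def _emit(chrom: str, iv: tuple[int, int]) -> None:
        nonlocal gid
        gid += 1
        strand = "+" if rng.uniform() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{gid:05d}",
                chrom=chrom,
                start=iv[0] + 1,
                end=iv[1],
                strand=strand,
            )
        )

    if truth is not None:
        for sweep in truth.sweep_intervals:
            for _ in range(genes_per_sweep):
                iv = _try_place(sweep.chrom, sweep.start, sweep.end)
                if iv is None:
                    raise ValueError(f"cannot place gene inside sweep {sweep}")
                _emit(sweep.chrom, iv)

    chrom_cycle = list(chrom_lengths)
    while len(genes) < n_genes:
        chrom = chrom_cycle[int(rng.integers(0, len(chrom_cycle)))]
        iv = _try_place(chrom, 0, chrom_lengths[chrom])
        if iv is None:
            raise ValueError("cannot pack requested number of genes")
        _emit(chrom, iv)

    genes.sort(key=lambda g: (g.chrom, g.start))
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c, length in chrom_lengths.items():
                fh.write(f"##sequence-region {c} 1 {length}\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                    f"\t.\tID={g.gene_id}\n"
                )
    return genes


# ---------------------------------------------------------------------------
# CDS pair evolution

_SENSE_CODONS: list[str] | None = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from .allele_evolution import STOP_CODONS

        bases = "ACGT"
        _SENSE_CODONS = [
            a + b + c
            for a in bases
            for b in bases
            for c in bases
            if a + b + c not in STOP_CODONS
        ]
    return _SENSE_CODONS


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def simulate_cds_pairs(
    n_pairs: int,
    n_codons: int,
    dnds: float,
    kappa: float = 1.0,
    divergence: float = 0.1,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Evolve ``(pair_id, cds_a, cds_b)`` tuples under a target dN/dS.

    ``cds_b`` derives from ``cds_a`` through ``Poisson(divergence * 3 *
    n_codons)`` proposed point mutations (transition bias ``kappa``):
    synonymous proposals are accepted with probability ``min(1, 1/dnds)``
    and nonsynonymous ones with ``min(1, dnds)``, so accepted changes
    realise the target ratio; proposals creating a stop codon are
    rejected.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if dnds <= 0:
        raise ValueError("dnds must be positive")
    from .allele_evolution import GENETIC_CODE, STOP_CODONS

    rng = np.random.default_rng(seed)
    sense = _sense_codons()
    p_syn = min(1.0, 1.0 / dnds)
    p_non = min(1.0, dnds)
    out: list[tuple[str, str, str]] = []
    for k in range(n_pairs):
        codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
        a = "".join(codons)
        b = list(a)
        n_prop = rng.poisson(divergence * 3 * n_codons)
        for _ in range(n_prop):
            site = int(rng.integers(0, 3 * n_codons))
            old = b[site]
            if rng.uniform() < kappa / (kappa + 2.0):
                new = _TRANSITION[old]
            else:
                tv = [x for x in "ACGT" if x != old and x != _TRANSITION[old]]
                new = tv[int(rng.integers(0, 2))]
            ci = site // 3
            codon_old = "".join(b[3 * ci : 3 * ci + 3])
            codon_new = (
                codon_old[: site % 3] + new + codon_old[site % 3 + 1 :]
            )
            if codon_new in STOP_CODONS:
                continue
            syn = GENETIC_CODE[codon_old] == GENETIC_CODE[codon_new]
            accept_p = p_syn if syn else p_non
            if rng.uniform() < accept_p:
                b[site] = new
        out.append((f"pair{k + 1:04d}", a, "".join(b)))
    return out


def write_cds_pair_fastas(
    pairs: Sequence[tuple[str, str, str]],
    fasta_a: str | Path,
    fasta_b: str | Path,
    pairs_tsv: str | Path,
) -> None:
    """Write the two allele FASTAs and the pairing table."""
    with open(fasta_a, "w") as fa, open(fasta_b, "w") as fb, open(
        pairs_tsv, "w"
    ) as ft:
        for pair_id, a, b in pairs:
            fa.write(f">{pair_id}|a\n{a}\n")
            fb.write(f">{pair_id}|b\n{b}\n")
            ft.write(f"{pair_id}|a\t{pair_id}|b\n")


def simulate_expression_pairs(
    n_pairs: int,
    frac_dea: float = 0.3,
    lfc_magnitude: float = 2.0,
    noise_sd: float = 0.2,
    stages: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Allele-pair expression table plus true DEA/EEA labels.

    EEA pairs share a stage mean; DEA pairs carry ``|log2FC| =
    lfc_magnitude`` (random sign) in one randomly chosen stage.
    Log-normal noise of ``noise_sd`` (log2 units) multiplies every value.
    """
    if not (0.0 <= frac_dea <= 1.0):
        raise ValueError("frac_dea must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dea = int(round(frac_dea * n_pairs))
    is_dea = np.zeros(n_pairs, dtype=bool)
    is_dea[rng.choice(n_pairs, size=n_dea, replace=False)] = True
    rows = []
    labels = {}
    for k in range(n_pairs):
        pair_id = f"pair{k + 1:04d}"
        labels[pair_id] = "DEA" if is_dea[k] else "EEA"
        dea_stage = int(rng.integers(0, stages)) if is_dea[k] else -1
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        for s in range(stages):
            base = rng.uniform(5.0, 50.0)
            lfc = lfc_magnitude * sign if s == dea_stage else 0.0
            ea = base * 2.0 ** (lfc + rng.normal(0.0, noise_sd) if noise_sd else lfc)
            eb = base * 2.0 ** (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            rows.append(
                {
                    "pair_id": pair_id,
                    "stage": f"stage{s + 1}",
                    "expr_a": ea,
                    "expr_b": eb,
                }
            )
    table = pd.DataFrame(rows)
    return table, pd.Series(labels, name="true_label").sort_index()


def simulate_telomeric_fasta(
    chrom_lengths: Mapping[str, int],
    repeats_per_end: int = 100,
    seed: int = 0,
    out_path: str | Path | None = None,
    motif: str = "TTTAGGG",
) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Chromosome sequences with exact telomeric arrays at both termini.

    The forward motif is planted at the 5' end and its reverse complement
    at the 3' end; the interior is uniform random sequence.  Returns the
    sequences and the truth counts per end.
    """
    rng = np.random.default_rng(seed)
    arr_len = repeats_per_end * len(motif)
    seqs: dict[str, str] = {}
    truth: dict[str, dict[str, int]] = {}
    rc = motif.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    for chrom, length in chrom_lengths.items():
        if 2 * arr_len >= length:
            raise ValueError(f"{chrom}: telomere arrays exceed half the length")
        interior = "".join(
            np.array(list("ACGT"), dtype=object)[
                rng.integers(0, 4, size=length - 2 * arr_len)
            ]
        )
        # scrub chance motif hits so the planted counts are exact truth
        while motif in interior or rc in interior:
            interior = interior.replace(motif, motif[:-1] + "C").replace(
                rc, rc[:-1] + "G"
            )
        seqs[chrom] = motif * repeats_per_end + interior + rc * repeats_per_end
        truth[chrom] = {"start": repeats_per_end, "end": repeats_per_end}
    if out_path is not None:
        with open(out_path, "w") as fh:
            for chrom, seq in seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    return seqs, truth


def simulate_ld_genotypes(
    n_sites: int = 500,
    spacing_bp: int = 2_000,
    n_samples: int = 40,
    decay_bp: float = 50_000.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Genotypes with distance-decaying LD from a haplotype copying model.

    Along each of the ``2 * n_samples`` haplotypes, the allele at a site
    copies the previous site's allele with probability
    ``exp(-distance / decay_bp)`` and is otherwise redrawn from the site
    frequency, giving pairwise correlation that decays roughly as
    ``exp(-d / decay_bp)``.  Smaller ``decay_bp`` means faster LD decay.
    """
    rng = np.random.default_rng(seed)
    pos = (np.arange(n_sites) + 1) * spacing_bp
    freq = rng.uniform(0.1, 0.9, size=n_sites)
    rho = np.exp(-spacing_bp / decay_bp)
    hap = np.empty((n_sites, 2 * n_samples), dtype=np.int8)
    hap[0] = rng.uniform(size=2 * n_samples) < freq[0]
    for i in range(1, n_sites):
        copy = rng.uniform(size=2 * n_samples) < rho
        fresh = (rng.uniform(size=2 * n_samples) < freq[i]).astype(np.int8)
        hap[i] = np.where(copy, hap[i - 1], fresh)
    dosage = (hap[:, ::2] + hap[:, 1::2]).astype(np.int8)
    if missing_rate > 0:
        mask = rng.uniform(size=dosage.shape) < missing_rate
        dosage[mask] = MISSING
    ref, alt = _simulate_alleles(rng, n_sites)
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=pos.astype(np.int64),
        ref_allele=ref,
        alt_allele=alt,
        dosage=dosage,
        sample_ids=[f"s{i:03d}" for i in range(n_samples)],
        contig_lengths={chrom: int(pos[-1] + spacing_bp)},
    )
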