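"""Readers and writers for the standard formats the scan touches.

Coordinate conventions are fixed at this boundary: VCF positions (1-based)
and GFF3 gene coordinates (1-based inclusive) are kept as such on the domain
types that mirror those formats, while all *internal* interval arithmetic
uses 0-based half-open :class:`GenomicInterval` (BED convention).  A VCF
site at position ``p`` occupies the internal interval ``[p - 1, p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "INFO_KEYS",
    "InputError",
    "FormatError",
    "GenomicInterval",
    "GeneModel",
    "PopulationMap",
    "GenotypeMatrix",
    "read_vcf",
    "read_population_map",
    "read_gff3",
    "write_bed",
    "read_bed",
]

#: Sentinel dosage for a missing (uncalled) genotype.
MISSING: int = -1

#: INFO annotations consulted by the hard-filter stage.
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")

_BASES = frozenset("ACGT")


class InputError(Exception):
    """Input is absent, unreadable or empty."""


class FormatError(Exception):
    """Input exists but violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene feature in GFF3 convention (1-based, inclusive ends)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def interval(self) -> GenomicInterval:
        """The gene footprint as an internal 0-based half-open interval."""
        return GenomicInterval(self.chrom, self.start - 1, self.end)


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of sample ids to population labels."""

    assignments: Mapping[str, str]

    def samples(self, label: str) -> list[str]:
        return [s for s, l in self.assignments.items() if l == label]

    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for l in self.assignments.values():
            out[l] = out.get(l, 0) + 1
        return out


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for sites x samples.

    ``dosage[i, j]`` is the ALT-allele count (0, 1, 2) of sample ``j`` at
    site ``i``, or :data:`MISSING`.  Sites are ordered by (chrom, pos) with
    positions strictly increasing within a chromosome; ``pos`` is 1-based as
    in VCF.  ``site_annotations`` maps INFO keys to per-site float arrays
    with ``nan`` where the annotation is absent.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    site_annotations: dict[str, np.ndarray] | None = None
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValueError("sample_ids not unique")
        if self.dosage.shape != (len(self.pos), len(self.sample_ids)):
            raise ValueError("dosage shape does not match sites x samples")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column indices of the given samples, in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        index = np.asarray(index)
        ann = None
        if self.site_annotations is not None:
            ann = {k: v[index] for k, v in self.site_annotations.items()}
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            dosage=self.dosage[index],
            sample_ids=list(self.sample_ids),
            site_annotations=ann,
            contig_lengths=self.contig_lengths,
        )


def read_vcf(path: str | Path, keep_info: bool = False) -> tuple[GenotypeMatrix, int]:
    """Read a VCF into a :class:`GenotypeMatrix` of biallelic SNPs.

    Multiallelic records and indels are skipped; the skip count is returned
    alongside the matrix.  Genotype phasing is ignored (dosage model);
    ``./.`` becomes :data:`MISSING`.  With ``keep_info``, the hard-filter
    INFO annotations are collected (``nan`` where a record lacks a key).
    Contig lengths are taken from ``##contig`` header lines when present.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    if not vcf.samples:
        raise FormatError(f"{path}: VCF has no sample columns")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    info: dict[str, list[float]] = {k: [] for k in INFO_KEYS} if keep_info else {}
    skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF.upper() not in _BASES
            or v.ALT[0].upper() not in _BASES
        ):
            skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF.upper())
        alts.append(v.ALT[0].upper())
        rows.append(gt)
        if keep_info:
            for k in INFO_KEYS:
                val = v.INFO.get(k)
                info[k].append(float(val) if val is not None else np.nan)

    contig_lengths = None
    if vcf.seqnames and vcf.seqlens:
        lens = dict(zip(vcf.seqnames, vcf.seqlens))
        # cyvcf2 reports 0 for contigs declared without a length
        contig_lengths = {c: n for c, n in lens.items() if n > 0} or None

    n_samples = len(vcf.samples)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=(
            np.vstack(rows)
            if rows
            else np.empty((0, n_samples), dtype=np.int8)
        ),
        sample_ids=list(vcf.samples),
        site_annotations=(
            {k: np.array(vals, dtype=float) for k, vals in info.items()}
            if keep_info
            else None
        ),
        contig_lengths=contig_lengths,
    )
    return gm, skipped


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a two-column TSV (sample id, population label).

    An optional header row ``sample<TAB>population`` (any case) is skipped.
    Duplicate sample ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            sample, label = (f.strip() for f in fields)
            if lineno == 1 and sample.lower() in {"sample", "sample_id", "id"}:
                continue
            if not sample or not label:
                raise FormatError(f"{path}:{lineno}: empty field")
            if sample in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = label
    if not assignments:
        raise InputError(f"{path}: population map is empty")
    return PopulationMap(assignments=assignments)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene features (type ``gene`` only) from a GFF3 file.

    Coordinates are kept 1-based inclusive, as in the file.  Every gene
    record must carry an ``ID`` attribute.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as e:
        raise FormatError(f"cannot parse GFF3 {path}: {e}") from e
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if "ID" not in feat.attributes:
            raise FormatError(f"{path}: gene at {feat.seqid}:{feat.start} lacks ID")
        genes.append(
            GeneModel(
                gene_id=feat.attributes["ID"][0],
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
            )
        )
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise FormatError(f"{path}: duplicate gene IDs")
    return genes


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    scores: Mapping[GenomicInterval, float] | None = None,
    names: Mapping[GenomicInterval, str] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start).

    With ``scores``/``names`` provided, emits BED5 columns
    (chrom, start, end, name, score); otherwise BED3.
    """
    ivs = sorted(intervals)
    with open(path, "w") as fh:
        for iv in ivs:
            if scores is None and names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                name = names.get(iv, ".") if names else "."
                score = scores.get(iv, 0.0) if scores else 0.0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:.6g}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read the first three BED columns back into intervals."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out
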