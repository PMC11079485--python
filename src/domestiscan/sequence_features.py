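"""Telomeric repeat-motif counting in terminal chromosome windows.

Plant telomeres carry tandem arrays of the heptamer TTTAGGG (reverse
complement CCCTAAA).  For each chromosome end we count non-overlapping
occurrences of the motif and of its reverse complement within a terminal
window (default 50 kb) and report the larger orientation per end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = ["TelomereReport", "count_telomere_repeats", "scan_fasta_telomeres"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TelomereReport:
    """Motif count in one terminal window of one chromosome."""

    chrom: str
    end_label: str  # "start" | "end"
    motif_count: int
    window_bp: int

    def __post_init__(self) -> None:
        if self.end_label not in {"start", "end"}:
            raise ValueError("end_label must be 'start' or 'end'")
        if self.motif_count < 0:
            raise ValueError("negative motif count")


def count_telomere_repeats(
    sequence: str,
    motif: str = "TTTAGGG",
    window_bp: int = 50_000,
    chrom: str = "chr",
) -> tuple[TelomereReport, TelomereReport]:
    """Count non-overlapping motif occurrences in both terminal windows.

    Both the motif and its reverse complement are counted in the first and
    last ``window_bp`` of the sequence (case-insensitive; N never
    matches); each end reports the larger of the two orientations.
    A sequence shorter than the motif yields zero counts; an empty
    sequence is an error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    motif = motif.upper()
    rc = _revcomp(motif)
    window = min(window_bp, len(seq))
    head = seq[:window]
    tail = seq[-window:]
    # str.count is non-overlapping greedy left-to-right
    start_count = max(head.count(motif), head.count(rc))
    end_count = max(tail.count(motif), tail.count(rc))
    return (
        TelomereReport(chrom, "start", start_count, window),
        TelomereReport(chrom, "end", end_count, window),
    )


def scan_fasta_telomeres(
    fasta_path: str | Path, motif: str = "TTTAGGG", window_bp: int = 50_000
) -> pd.DataFrame:
    """Telomere-repeat report for every sequence in a FASTA file."""
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        for report in count_telomere_repeats(
            str(record.seq), motif=motif, window_bp=window_bp, chrom=record.id
        ):
            rows.append(
                {
                    "chrom": report.chrom,
                    "end_label": report.end_label,
                    "motif_count": report.motif_count,
                    "window_bp": report.window_bp,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "end_label", "motif_count", "window_bp"])
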