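#!/usr/bin/env python
"""Telomere-motif survey: plant known TTTAGGG arrays at chromosome ends,
scan the terminal 50 kb, and confirm the counts round-trip.
"""

import argparse
from pathlib import Path

from domestiscan import synthetic_data as sd
from domestiscan.sequence_features import scan_fasta_telomeres


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--repeats", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fasta = args.out / "telomere_genome.fa"
    _, truth = sd.simulate_telomeric_fasta(
        {"chr1": 300_000, "chr2": 300_000},
        repeats_per_end=args.repeats, seed=args.seed, out_path=fasta,
    )
    table = scan_fasta_telomeres(fasta, window_bp=50_000)
    table.to_csv(args.out / "telomeres.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    exact = all(
        int(row["motif_count"]) == truth[row["chrom"]][row["end_label"]]
        for _, row in table.iterrows()
    )
    print(f"planted {args.repeats} repeats per end; "
          f"counts recovered exactly: {exact}")
    print(f"wrote {args.out/'telomeres.tsv'}")


if __name__ == "__main__":
    main()
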