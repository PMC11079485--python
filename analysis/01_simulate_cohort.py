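#!/usr/bin/env python
"""Generate the study cohort: a two-population (wild / cultivated) SNP
panel on a 10-Mb, two-chromosome genome with five planted 300-kb sweeps,
plus gene models, written under results/sim/.

The cohort is the input for every downstream analysis step; the planted
sweep intervals are the ground truth against which the scan is scored.
"""

import argparse
from pathlib import Path

from domestiscan import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    params = sd.SimParams()
    vcf, popmap, truth = sd.simulate_two_pop_vcf(params, args.seed, args.out)
    genes = sd.simulate_gff(
        params.chrom_lengths(), n_genes=200, seed=args.seed, truth=truth,
        genes_per_sweep=2, out_path=args.out / "genes.gff3",
    )
    print(f"cohort: {params.n_wild} wild + {params.n_cult} cultivated diploids")
    print(f"genome: {params.n_chrom} x {params.chrom_length/1e6:.0f} Mb, "
          f"~{params.snp_density*1000:.0f} SNP/kb, background F={params.fst}")
    print(f"planted sweeps ({len(truth.sweep_intervals)}):")
    for iv in truth.sweep_intervals:
        print(f"  {iv.chrom}:{iv.start}-{iv.end}")
    print(f"genes: {len(genes)} (>=2 forced into each sweep)")
    print(f"wrote {vcf}, {popmap}, {args.out/'genes.gff3'}, {args.out/'truth.json'}")


if __name__ == "__main__":
    main()
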