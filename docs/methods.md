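# Methods

`domestiscan` implements the population-genomic scan used to locate
domestication sweeps in a crop/wild-progenitor pair, together with the
surrounding analyses (SNP quality filtering, LD decay, allele-pair Ka/Ks
and expression divergence, telomere-motif counting) and a synthetic-data
generator that produces every input with the statistical structure the
scan assumes. This note records the models, the defaults and why, the
numerical choices, and what the synthetic experiments do and do not
demonstrate.

## The scan statistics

**Nucleotide diversity (π).** Per site, the unbiased mean pairwise
difference among the `n` called alleles, `π_site = ref·alt / C(n,2)`,
which handles per-site missingness naturally. Per window, the sum of
site values divided by the *full* window length in bp — the VCFtools
`--window-pi` convention, under which unsampled and monomorphic
positions contribute zero difference but full length. Windows are
100 kb sliding by 10 kb by default; final windows are truncated at the
chromosome end and the truncated length is the denominator.

**F_ST.** The Weir & Cockerham (1984) two-population diploid estimator.
Per site we compute the three variance components — `a` (between
populations), `b` (between individuals within populations), `c` (within
individuals) — from per-population genotype counts, and report the
window-level "weighted" estimate `Σa / Σ(a+b+c)` over informative sites
(the ratio-of-sums, as VCFtools' `WEIGHTED_FST`). Negative values are
reported as-is; sites whose component sum is not positive are excluded;
a window with no informative site is NA. Hudson-style estimators are
deliberately not offered: one estimator, one definition.

**ROD.** `ROD = 1 − π_cultivated / π_wild`. The domesticate is always
population 1, so a sweep in the domesticate drives ROD toward 1; values
are negative where the domesticate is *more* diverse. ROD is NA when
wild π is zero; NA windows are excluded from quantile computation and
can never be selected.

**Sweep calling.** Thresholds are empirical upper-tail cut points at the
top 5% of the *defined* window values, using the nearest-rank quantile
(the value at ascending rank `⌈0.95·n⌉`, no interpolation) with strict
`>` selection. Nearest-rank makes the "at most 5% selected" property
exact, and strict inequality means a degenerate constant statistic
selects nothing. A window is called iff *both* F_ST and ROD exceed their
thresholds. Overlapping or book-ended selected windows merge into
regions (with a 10-kb step and 100-kb windows, consecutive selected
windows always overlap); region scores are member maxima. Genes attach
to a region when their footprint overlaps it by ≥1 bp, comparing the
1-based inclusive gene coordinates as the half-open interval
`[start−1, end)`.

**Coordinates.** Everything internal is 0-based half-open; VCF (1-based)
and GFF3 (1-based inclusive) are converted at the I/O boundary, and a
VCF site at position `p` occupies `[p−1, p)`. BED output follows its
native convention unchanged.

## The SNP quality funnel

1. **Hard filters** — the GATK-style disjunction `QD < 2.0 || MQ < 40.0
   || FS > 60.0 || SOR > 3.0 || MQRankSum < −12.5 || ReadPosRankSum <
   −8.0`. A site lacking an annotation is never removed by that rule
   (GATK's own convention for missing annotations); all inequalities are
   strict, so a site at exactly QD = 2.0 survives.
2. **MAF / call rate** — keep sites with MAF strictly above 0.01
   (computed over called alleles only) and genotype call rate ≥ 0.9.
   The source description of the missingness cut is ambiguous between
   "missingness > 0.9 removed" and "call rate > 0.9 kept"; we read it as
   a call-rate floor of 0.9 (inclusive), the only reading that yields a
   well-genotyped panel.
3. **LD pruning** — PLINK-style `--indep-pairwise 50 10 0.2` semantics:
   sliding windows of 50 SNPs advancing by 10 within each chromosome;
   while any kept pair in a window has dosage-r² above 0.2, the
   lower-MAF member of the first offending pair (position order) is
   removed, ties removing the larger position. Windows slide over the
   *surviving* sites and passes repeat until stable, so the contract —
   no within-window kept pair above the threshold — holds exhaustively
   on the output. Bit-exact agreement with PLINK is not promised; the
   postcondition is. Pruning is applied jointly across populations (the
   source does not say; a per-population option is a config flag away)
   and is *off* by default in the sweep-scan pipeline, since pruning
   removes exactly the LD a sweep creates; it exists for the
   structure/phylogeny-style site sets.

r² is the squared Pearson correlation of unphased genotype dosages over
samples called at both sites (PLINK's default for unphased data),
undefined for constant vectors or fewer than two shared calls. The LD
decay curve averages r² over all same-chromosome pairs within a 1000-kb
horizon in fixed bins (1 kb default; only the horizon is prescribed by
the source analysis, the bin width is ours).

## Allele-pair evolution

**NG86 Ka/Ks.** Nei–Gojobori (1986) with equal pathway weighting:
synonymous site counts per codon are the fraction of the three possible
changes per position that preserve the amino acid (changes to stop
codons count as nonsynonymous), averaged over the two sequences;
observed multi-difference codons are resolved by averaging over all
orderings of the single-base steps, excluding pathways that pass through
a stop codon (a codon pair whose every pathway does so is skipped);
proportions are Jukes–Cantor corrected, `d = −(3/4)·ln(1 − 4p/3)`,
undefined at `p ≥ 3/4`. `Ka/Ks` is undefined when Ks is zero or either
distance is undefined. The source work used a GUI tool without naming
the estimator; NG86+JC was chosen because it is standard, assumption-
light, and checkable by hand on small fixtures. Codons containing
ambiguity characters are skipped pairwise.

Selection classes follow the published cut points: `Ka/Ks < 0.1`
purifying, `> 1` positive, the closed interval `[0.1, 1]` intermediate,
undefined ratios reported as their own class. Class percentages are
kept at full precision and rounded only for display.

**DEA/EEA.** Per stage, `log2FC = log2((a + 1)/(b + 1))` with a
pseudocount of 1.0 on normalized expression (the source is silent on
zero handling; a pseudocount of one unit of normalized expression is the
conventional choice). A pair is a differentially expressed allele pair
(DEA) iff any stage reaches `|log2FC| ≥ 1` (inclusive, per the published
rule); otherwise it is an equivalently expressed pair (EEA). Swapping
the alleles flips the sign of every fold change but never the label.

## Telomere counting

Non-overlapping occurrences of TTTAGGG and of its reverse complement
CCCTAAA are counted in the first and last 50 kb of each chromosome
sequence (case-insensitive, N never matches; the heptamer cannot
overlap itself, so greedy counting is exact), and each end reports the
larger orientation.

## The synthetic-data generator

The generator defines the study conditions for every test; its defaults
are fixed once and are not tuned per experiment.

**Two-population cohort.** Per SNP, an ancestral frequency
`p ~ U(0.05, 0.95)`; wild and cultivated frequencies are each drawn from
the Balding–Nichols beta distribution around `p` with divergence
parameter `F` (default 0.05, a realistic crop/wild genome-wide value).
Drawing *both* populations from the model makes `F` the expectation of
the Weir–Cockerham estimate, giving the estimator-recovery tests a
closed-form target. Inside planted sweep intervals the cultivated
frequency is pushed to the nearer fixation state with probability 0.9
per site, producing near-zero cultivated π (ROD → 1) and elevated F_ST
without simulating hitchhiking dynamics — sufficient to exercise the
dual-threshold intersection, and much cheaper than a coalescent.
Genotypes are `Binomial(2, freq)` per diploid; 2% of genotypes are
masked missing; INFO annotations are drawn from comfortably passing
ranges except a planted 2% of sites that violate one randomly chosen
hard-filter rule. Defaults: two 5-Mb chromosomes at one SNP per kb,
40 diploids per population, five 300-kb sweeps. These desk-scale sizes
keep every simulation comfortably fast while leaving ≈2000 sites per
chromosome and ≈100 SNPs per 100-kb window, enough for stable window
statistics.

**Limitations of the cohort model:** sites are independent given their
frequencies (no background LD, no recombination map), there is no
demography, no allele-frequency spectrum shaped by mutation/drift
balance, and sweeps are frequency pushes rather than hitchhiking.
Passing recovery tests therefore demonstrates the *estimators and the
calling logic*, not robustness to linked selection or complex
demography in real data.

**LD genotypes.** A separate haplotype copying model: along each
haplotype the allele at a site copies the previous site with probability
`exp(−d/L)` and is otherwise redrawn from the site frequency, giving
pairwise correlation decaying approximately as `exp(−d/L)`. Wild-like
and cultivated-like settings differ only in `L` (shorter for wild),
reproducing the qualitative wild-faster-than-cultivated decay ordering
at the level at which it is testable on simulated data.

**CDS pairs.** One sequence of sense codons is mutated by
`Poisson(t·3L)` proposed point mutations (transition bias `kappa`,
default 1.0 to match the equal-rates assumption of NG86; divergence `t`
default 0.1 per nt so that multiple hits stay modest); synonymous
proposals are accepted with probability `min(1, 1/ω)` and nonsynonymous
with `min(1, ω)`, so accepted changes realise the target dN/dS `ω`;
stop-creating proposals are rejected. Recovery tests at ω ∈ {0.1, 1.0}
come back within 20%, with the residual downward bias at ω = 1 coming
from multiple hits at the same codon.

**Expression pairs.** EEA pairs share a per-stage mean (U(5, 50)); DEA
pairs (a chosen fraction) carry `|log2FC| = 2` in one random stage;
log-normal noise with `σ = 0.2` in log2 units multiplies both alleles.
With the pseudocount, a planted fold change of 2 on these magnitudes
yields observed `|log2FC| ≈ 1.8–2.0`, safely past the threshold, so
noiseless recovery is exact and noisy recovery is within a few
percentage points.

**Telomeric FASTA.** Exact motif arrays planted at both termini with a
random interior; chance interior occurrences of either orientation are
scrubbed so the planted counts are exact ground truth.

Every generator is a pure function of (parameters, seed); fixed seeds
give byte-identical files.

## Pipeline and reproducibility

`run_scan` executes read → filter → windows → sweep → genes → report,
logging to console and a run-local file, and writes `summary.json`
(per-stage counts and the realized thresholds), `windows.tsv`,
`regions.bed`, `regions.tsv`, `genes.txt`, and a manifest with the
package version, the effective config, its hash and input checksums.
Stage failures abort with a stage-labelled error and remove partial
outputs. Config files are flat `key=value`; CLI flags override file
values. `scripts/acceptance.py --seed N --out f.json` regenerates all
inputs from the given seed and recomputes the headline quantities; the
problem sizes it uses are the generator defaults above plus a 2-Mb
single-chromosome cohort (~2000 sites) for the F_ST recovery and 50
pairs × 2000 codons for the Ka/Ks recovery.

## Known limitations

- The published genome-scale numbers (30.5 M SNPs, 389 sweep regions,
  300 sweep genes, the 0.041/0.569 thresholds) are properties of the
  full 672-accession resequencing panel and its assemblies; they cannot
  be recomputed at desk scale and this package does not attempt to.
  What is reproduced is the method — the statistics, the filters, the
  thresholds' *definition* — and the published worked-example
  percentages, which are pure arithmetic.
- The merge rule for selected windows (overlap or book-ended) is our
  explicit choice; the source does not state one.
- NG86 underestimates rates under strong transition bias or extreme
  codon usage; a likelihood codon model is out of scope.
- The windowed scan assumes one shared window set for π, F_ST and ROD;
  per-statistic anchoring offsets are not supported.
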