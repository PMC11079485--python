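"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from textbook definitions with explicit loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = -1


def brute_pi_window(dosage, positions, pop_cols, win_start, win_end):
    """Window pi by explicit double loop over sampled allele pairs.

    ``dosage`` is sites x samples; a site at 1-based position p lies in
    the window iff win_start < p <= win_end.  Returns the summed mean
    pairwise difference divided by the window length.
    """
    total = 0.0
    for i, p in enumerate(positions):
        if not (win_start < p <= win_end):
            continue
        alleles = []
        for j in pop_cols:
            d = dosage[i][j]
            if d == MISSING:
                continue
            alleles.extend([1] * int(d) + [0] * (2 - int(d)))
        n = len(alleles)
        if n < 2:
            continue
        diff = 0
        npairs = 0
        for a, b in itertools.combinations(range(n), 2):
            npairs += 1
            if alleles[a] != alleles[b]:
                diff += 1
        total += diff / npairs
    return total / (win_end - win_start)


def wc_components_scalar(counts1, counts2):
    """Weir & Cockerham (1984) two-population variance components,
    transcribed term by term from the published estimator.

    ``counts*`` are (hom_ref, het, hom_alt) genotype counts.
    """
    n1 = sum(counts1)
    n2 = sum(counts2)
    p1 = (counts1[1] + 2 * counts1[2]) / (2 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def brute_weighted_fst(dosage, positions, cols1, cols2, win_start, win_end):
    """Window ratio-of-sums F_ST from the scalar component oracle."""
    num = 0.0
    den = 0.0
    for i, p in enumerate(positions):
        if not (win_start < p <= win_end):
            continue
        g1 = _gcounts(dosage[i], cols1)
        g2 = _gcounts(dosage[i], cols2)
        if sum(g1) < 1 or sum(g2) < 1:
            continue
        a, b, c = wc_components_scalar(g1, g2)
        if a + b + c > 0:
            num += a
            den += a + b + c
    return num / den if den > 0 else float("nan")


def _gcounts(row, cols):
    hr = het = ha = 0
    for j in cols:
        if row[j] == 0:
            hr += 1
        elif row[j] == 1:
            het += 1
        elif row[j] == 2:
            ha += 1
    return (hr, het, ha)


def brute_r2(x, y):
    """Squared Pearson correlation over jointly called samples, by the
    definitional sums."""
    pairs = [(a, b) for a, b in zip(x, y) if a != MISSING and b != MISSING]
    if len(pairs) < 2:
        return float("nan")
    xs = [float(a) for a, _ in pairs]
    ys = [float(b) for _, b in pairs]
    n = len(pairs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    vx = sum((a - mx) ** 2 for a in xs)
    vy = sum((b - my) ** 2 for b in ys)
    if vx == 0 or vy == 0:
        return float("nan")
    return (cov * cov) / (vx * vy)


def brute_ld_bins(dosage, positions, max_dist, bin_width):
    """All-pairs distance-binned mean r^2 by exhaustive enumeration."""
    n_bins = math.ceil(max_dist / bin_width)
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            d = abs(int(positions[j]) - int(positions[i]))
            if d > max_dist:
                continue
            r2 = brute_r2(dosage[i], dosage[j])
            if math.isnan(r2):
                continue
            b = min(d // bin_width, n_bins - 1)
            sums[b] += r2
            counts[b] += 1
    means = [s / c if c else float("nan") for s, c in zip(sums, counts)]
    return means, counts
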