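"""Windowed population-genetic statistics: nucleotide diversity (pi),
Weir-Cockerham F_ST, and the reduction-of-diversity (ROD) statistic.

The scan statistic of a domestication study is computed in overlapping
sliding windows (default 100 kb advancing by 10 kb).  Per window we report

* ``pi`` per population: the sum of per-site unbiased mean pairwise
  differences divided by the *full* window length in bp (monomorphic and
  unsampled positions contribute zero difference but full length, the
  VCFtools ``--window-pi`` convention);
* the Weir & Cockerham (1984) two-population F_ST as the ratio of summed
  variance components ``sum(a) / sum(a + b + c)`` ("weighted" estimate);
* ``ROD = 1 - pi_pop1 / pi_pop2`` with pop1 the domesticate and pop2 the
  wild population, so a sweep in the domesticate drives ROD toward 1.

Undefined values (no informative site; pi_pop2 = 0) are ``nan`` and are
excluded from downstream quantile computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenomicInterval, GenotypeMatrix

__all__ = [
    "WindowSpec",
    "make_windows",
    "site_pi",
    "allele_counts",
    "windowed_pi",
    "site_fst_components",
    "windowed_fst",
    "rod",
    "compute_window_stats",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in bp."""

    size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")


def make_windows(
    chrom_lengths: Mapping[str, int], spec: WindowSpec = WindowSpec()
) -> list[GenomicInterval]:
    """Sliding windows ``[k*step, k*step + size)`` truncated at chromosome ends.

    Windows are generated while their start lies inside the chromosome, so
    every bp is covered by at least one window.
    """
    windows: list[GenomicInterval] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        start = 0
        while start < length:
            windows.append(GenomicInterval(chrom, start, min(start + spec.size, length)))
            start += spec.step
    return windows


def site_pi(ref_count: int | np.ndarray, alt_count: int | np.ndarray) -> float | np.ndarray:
    """Per-site nucleotide diversity from called allele counts.

    The unbiased mean pairwise difference among the ``n = ref + alt``
    sampled alleles: ``ref * alt / C(n, 2)``.  Sites with fewer than two
    called alleles are undefined (``nan``).
    """
    r = np.asarray(ref_count, dtype=float)
    a = np.asarray(alt_count, dtype=float)
    n = r + a
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(n >= 2, (r * a) / (n * (n - 1) / 2.0), np.nan)
    if np.ndim(ref_count) == 0 and np.ndim(alt_count) == 0:
        return float(out)
    return out


def allele_counts(
    gm: GenotypeMatrix, sample_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (REF, ALT) called-allele counts over the given samples."""
    cols = gm.sample_indices(sample_ids)
    d = gm.dosage[:, cols]
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=1)
    ref = 2 * called.sum(axis=1) - alt
    return ref.astype(np.int64), alt.astype(np.int64)


def _window_site_slices(
    gm: GenotypeMatrix, windows: Sequence[GenomicInterval]
) -> list[np.ndarray]:
    """For each window, the indices of sites whose [pos-1, pos) lies in it."""
    by_chrom: dict[str, np.ndarray] = {}
    for c in np.unique(gm.chrom):
        by_chrom[str(c)] = np.flatnonzero(gm.chrom == c)
    out: list[np.ndarray] = []
    for w in windows:
        idx = by_chrom.get(w.chrom)
        if idx is None:
            out.append(np.empty(0, dtype=int))
            continue
        p = gm.pos[idx]  # 1-based; internal site interval is [p-1, p)
        lo = np.searchsorted(p, w.start + 1, side="left")
        hi = np.searchsorted(p, w.end, side="right")
        out.append(idx[lo:hi])
    return out


def windowed_pi(
    gm: GenotypeMatrix,
    pop_samples: Sequence[str],
    windows: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-window pi (per bp) for one population.

    Sites with fewer than two called alleles in the population are skipped;
    the denominator is the full (possibly truncated) window length.
    """
    if len(pop_samples) == 0:
        raise ValueError("empty population")
    ref, alt = allele_counts(gm, pop_samples)
    persite = site_pi(ref, alt)
    persite = np.where(np.isnan(persite), 0.0, persite)
    out = np.empty(len(windows), dtype=float)
    for i, (w, idx) in enumerate(zip(windows, _window_site_slices(gm, windows))):
        out[i] = persite[idx].sum() / len(w)
    return out


def _genotype_counts(
    gm: GenotypeMatrix, sample_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = gm.sample_indices(sample_ids)
    d = gm.dosage[:, cols]
    hom_ref = (d == 0).sum(axis=1)
    het = (d == 1).sum(axis=1)
    hom_alt = (d == 2).sum(axis=1)
    return hom_ref, het, hom_alt


def site_fst_components(
    pop1_counts: Sequence[int] | np.ndarray,
    pop2_counts: Sequence[int] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) variance components for two diploid samples.

    Each argument holds per-site genotype counts ``(hom_ref, het, hom_alt)``
    — scalars or aligned arrays.  Returns the components ``(a, b, c)``:
    between-population, between-individual-within-population, and
    within-individual variance.  The per-site estimator is
    ``theta = a / (a + b + c)``; sites where the denominator is not
    positive are non-informative.
    """
    c1 = np.asarray(pop1_counts, dtype=float)
    c2 = np.asarray(pop2_counts, dtype=float)
    scalar = c1.ndim == 1
    if scalar:
        c1 = c1[:, None]
        c2 = c2[:, None]
    if c1.shape[0] != 3 or c1.shape != c2.shape:
        raise ValueError("counts must be (hom_ref, het, hom_alt), aligned")
    # per population: sample size (diploids), ALT freq, observed het freq
    n1 = c1.sum(axis=0)
    n2 = c2.sum(axis=0)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("each population needs >=1 called genotype per site")
    p1 = (c1[1] + 2 * c1[2]) / (2 * n1)
    p2 = (c2[1] + 2 * c2[2]) / (2 * n2)
    h1 = c1[1] / n1
    h2 = c2[1] / n2

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    # single-diploid populations make (nbar - 1) vanish; flag non-informative
    bad = ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    c = np.where(bad, 0.0, c)
    if scalar:
        return float(a[0]), float(b[0]), float(c[0])  # type: ignore[return-value]
    return a, b, c


def windowed_fst(
    gm: GenotypeMatrix,
    pop1_samples: Sequence[str],
    pop2_samples: Sequence[str],
    windows: Sequence[GenomicInterval],
) -> np.ndarray:
    """Per-window weighted Weir-Cockerham F_ST: ``sum(a)/sum(a+b+c)``.

    Sites with zero called genotypes in either population, or with a
    non-positive component sum, are excluded; windows with no informative
    site are ``nan``.  Negative window values are reported as-is.
    """
    if set(pop1_samples) & set(pop2_samples):
        raise ValueError("populations overlap")
    g1 = np.vstack(_genotype_counts(gm, pop1_samples))
    g2 = np.vstack(_genotype_counts(gm, pop2_samples))
    n1 = g1.sum(axis=0)
    n2 = g2.sum(axis=0)
    ok = (n1 >= 1) & (n2 >= 1)
    a = np.zeros(gm.n_sites)
    abc = np.zeros(gm.n_sites)
    if ok.any():
        ai, bi, ci = site_fst_components(g1[:, ok], g2[:, ok])
        a[ok] = ai
        abc[ok] = ai + bi + ci
    informative = ok & (abc > 0)
    out = np.empty(len(windows), dtype=float)
    for i, idx in enumerate(_window_site_slices(gm, windows)):
        sel = idx[informative[idx]]
        denom = abc[sel].sum()
        out[i] = a[sel].sum() / denom if denom > 0 else np.nan
    return out


def rod(pi_pop1: float | np.ndarray, pi_pop2: float | np.ndarray) -> float | np.ndarray:
    """Reduction of diversity: ``1 - pi_pop1 / pi_pop2``.

    pop1 is the domesticated population, pop2 the wild one; values near 1
    mark diversity loss in the domesticate.  Undefined (``nan``) when the
    wild diversity is zero.  Negative inputs are rejected.
    """
    p1 = np.asarray(pi_pop1, dtype=float)
    p2 = np.asarray(pi_pop2, dtype=float)
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("pi must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(p2 > 0, 1.0 - p1 / p2, np.nan)
    if np.ndim(pi_pop1) == 0 and np.ndim(pi_pop2) == 0:
        return float(out)
    return out


def compute_window_stats(
    gm: GenotypeMatrix,
    pop1_samples: Sequence[str],
    pop2_samples: Sequence[str],
    windows: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """One row per window: chrom, start, end, n_sites, pi_pop1, pi_pop2, fst, rod.

    pop1 is the domesticated (swept) population.  Starts/ends are 0-based
    half-open; undefined statistics are NaN.
    """
    slices = _window_site_slices(gm, windows)
    pi1 = windowed_pi(gm, pop1_samples, windows)
    pi2 = windowed_pi(gm, pop2_samples, windows)
    fst = windowed_fst(gm, pop1_samples, pop2_samples, windows)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": [len(s) for s in slices],
            "pi_pop1": pi1,
            "pi_pop2": pi2,
            "fst": fst,
            "rod": rod(pi1, pi2),
        }
    )
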