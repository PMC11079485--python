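"""Pairwise genotype linkage disequilibrium (r^2) and the distance-binned
LD-decay curve.

r^2 is the squared Pearson correlation of unphased genotype dosages
(PLINK's default for unphased data), computed over the samples called at
both sites.  The decay curve averages r^2 of all same-chromosome site
pairs up to a physical horizon (default 1000 kb) in fixed-width distance
bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

__all__ = ["pairwise_r2", "ld_decay", "LdDecayCurve"]


@dataclass(frozen=True)
class LdDecayCurve:
    """Mean r^2 per distance bin; bins are [bin_start, bin_end) in bp."""

    table: pd.DataFrame  # columns: bin_start, bin_end, mean_r2, n_pairs

    def total_pairs(self) -> int:
        return int(self.table["n_pairs"].sum())


def pairwise_r2(dosage_i: np.ndarray, dosage_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Restricted to samples called at both sites; undefined (``nan``) when
    fewer than two shared calls remain or either vector is constant over
    the shared calls.
    """
    x = np.asarray(dosage_i)
    y = np.asarray(dosage_j)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    m = (x != MISSING) & (y != MISSING)
    if m.sum() < 2:
        return float("nan")
    xf = x[m].astype(float)
    yf = y[m].astype(float)
    xf -= xf.mean()
    yf -= yf.mean()
    vx = (xf * xf).sum()
    vy = (yf * yf).sum()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    r = (xf * yf).sum() / np.sqrt(vx * vy)
    return float(r * r)


def _pairwise_r2_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r^2 of one site against a block of sites, missing-aware, vectorised."""
    called_x = x != MISSING
    called_b = block != MISSING
    m = called_b & called_x[None, :]
    n = m.sum(axis=1).astype(float)
    xf = x.astype(float)
    bf = block.astype(float)
    sx = np.where(m, xf[None, :], 0.0).sum(axis=1)
    sy = np.where(m, bf, 0.0).sum(axis=1)
    sxx = np.where(m, xf[None, :] ** 2, 0.0).sum(axis=1)
    syy = np.where(m, bf**2, 0.0).sum(axis=1)
    sxy = np.where(m, xf[None, :] * bf, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    pop_samples: Sequence[str],
    max_dist: int = 1_000_000,
    bin_width: int = 1_000,
) -> LdDecayCurve:
    """Distance-binned mean r^2 over all same-chromosome pairs within
    ``max_dist`` bp.

    Pairs with undefined r^2 are skipped.  Bins ``[k*bin_width,
    (k+1)*bin_width)`` cover (0, max_dist]; a pair's distance is
    ``|pos_i - pos_j|``.
    """
    cols = gm.sample_indices(pop_samples)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in np.unique(gm.chrom):
        idx = np.flatnonzero(gm.chrom == c)
        pos = gm.pos[idx]
        dos = gm.dosage[np.ix_(idx, cols)]
        for i in range(len(idx) - 1):
            hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            if hi <= i + 1:
                continue
            r2 = _pairwise_r2_block(dos[i], dos[i + 1 : hi])
            d = pos[i + 1 : hi] - pos[i]
            ok = ~np.isnan(r2)
            if not ok.any():
                continue
            # half-open bins [k*w, (k+1)*w); the last bin absorbs d == max_dist
            b = np.minimum(d[ok] // bin_width, n_bins - 1)
            np.add.at(sums, b, r2[ok])
            np.add.at(counts, b, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": np.minimum((np.arange(n_bins) + 1) * bin_width, max_dist),
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
    return LdDecayCurve(table=table)
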